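"""Canonical EEG frequency bands, zero-phase band-pass filtering, and band power.

The six bands tile 1-55 Hz with half-open ``[lo, hi)`` edges so that shared
edges (4, 8, 12, 18, 30 Hz) are never counted twice: band powers computed on a
common Welch grid sum exactly to the 1-55 Hz total.

Filtering is a 3rd-order Butterworth IIR applied forward and backward
(zero phase delay); power is a Welch periodogram with 1-s Hann segments and
50 % overlap, integrated bin-wise over the band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[lo, hi)`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not (0 < self.lo < self.hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi, got lo={self.lo}, hi={self.hi}"
            )


#: The canonical six-band set: delta, theta, alpha, low beta, high beta, gamma.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("low_beta", 12.0, 18.0),
    BandDefinition("high_beta", 18.0, 30.0),
    BandDefinition("gamma", 30.0, 55.0),
)

BAND_MAP: dict[str, BandDefinition] = {b.name: b for b in CANONICAL_BANDS}

#: Denominator range for relative band power (Hz, half-open).
TOTAL_RANGE: tuple[float, float] = (1.0, 55.0)

DEFAULT_FILTER_ORDER = 3  # per pass; applied forward-backward


def get_band(band: "BandDefinition | str") -> BandDefinition:
    """Resolve a band given either a definition or a canonical band name."""
    if isinstance(band, BandDefinition):
        return band
    try:
        return BAND_MAP[band]
    except KeyError:
        raise KeyError(
            f"unknown band {band!r}; canonical bands are {sorted(BAND_MAP)}"
        ) from None


def butter_bandpass_sos(band, fs: float, order: int = DEFAULT_FILTER_ORDER):
    """Second-order sections for the Butterworth band-pass used throughout."""
    band = get_band(band)
    if band.hi >= fs / 2:
        raise ValueError(
            f"band {band.name!r} upper edge {band.hi} Hz >= Nyquist {fs / 2} Hz"
        )
    return signal.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, fs: float, band, order: int = DEFAULT_FILTER_ORDER,
             axis: int = -1) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along ``axis``.

    Accepts any array shape; epochs stacked on leading axes are filtered
    independently, matching per-epoch filtering of source time series.
    """
    sos = butter_bandpass_sos(band, fs, order)
    return signal.sosfiltfilt(sos, np.asarray(x), axis=axis)


def welch_psd(x: np.ndarray, fs: float, axis: int = -1):
    """Welch PSD with 1-s Hann segments and 50 % overlap.

    Returns ``(freqs, psd)``; ``psd`` has the shape of ``x`` with ``axis``
    replaced by frequency bins. Requires at least one second of samples.
    """
    x = np.asarray(x)
    n = x.shape[axis]
    nperseg = int(round(fs))
    if n < nperseg:
        raise ValueError(
            f"signal too short for spectral estimation: {n} samples < 1 s ({nperseg})"
        )
    return signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                        noverlap=nperseg // 2, axis=axis)


def integrate_band(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float,
                   axis: int = -1) -> np.ndarray:
    """Bin-wise integral of a PSD over ``[lo, hi)`` (rectangle rule, df-spaced)."""
    df = freqs[1] - freqs[0]
    mask = (freqs >= lo) & (freqs < hi)
    return np.take(psd, np.flatnonzero(mask), axis=axis).sum(axis=axis) * df


def band_power(x: np.ndarray, fs: float, band, axis: int = -1) -> np.ndarray:
    """Power (signal units squared) of ``x`` in ``band`` via Welch integration."""
    band = get_band(band)
    freqs, psd = welch_psd(x, fs, axis=axis)
    return integrate_band(freqs, psd, band.lo, band.hi, axis=axis)


def relative_band_power(x: np.ndarray, fs: float, band,
                        total_range: tuple[float, float] = TOTAL_RANGE,
                        axis: int = -1) -> np.ndarray:
    """Band power divided by total power over ``total_range`` (default 1-55 Hz).

    On a common Welch grid the six canonical relative powers sum to 1.
    """
    band = get_band(band)
    freqs, psd = welch_psd(x, fs, axis=axis)
    bp = integrate_band(freqs, psd, band.lo, band.hi, axis=axis)
    total = integrate_band(freqs, psd, total_range[0], total_range[1], axis=axis)
    return bp / total
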