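"""Resting-state EEG screening: reference, filtering, EOG correction, epoching,
artifact and drowsiness rejection, and fixed-count epoch selection.

The screening chain turns a continuous multichannel recording into exactly the
epoch set the downstream analysis consumes:

1. average reference over the EEG (non-EOG) channels,
2. 1 Hz zero-phase high-pass (3rd-order Butterworth per pass) to remove DC,
3. least-squares regression of each EEG channel on the EOG channels,
4. division into consecutive non-overlapping fixed-length epochs,
5. rejection of epochs whose amplitude exceeds +-75 uV on any EEG channel,
6. rejection of drowsy epochs whose theta/alpha power ratio exceeds 1,
7. selection of the first ``n`` surviving epochs (30 by default).

Thresholds use strict inequality ("exceeding"). The pipeline order is fixed:
amplitude rejection precedes drowsiness rejection precedes selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import spectral
from .exceptions import InsufficientEpochsError

# Epoch status labels. Every epoch carries exactly one.
KEPT = "kept"
REJECTED_AMPLITUDE = "rejected_amplitude"
REJECTED_DROWSY = "rejected_drowsy"
NOT_SELECTED = "not_selected"
STATUSES = (KEPT, REJECTED_AMPLITUDE, REJECTED_DROWSY, NOT_SELECTED)

DEFAULT_AMPLITUDE_THRESHOLD_UV = 75.0
DEFAULT_EPOCH_LEN_S = 2.0
DEFAULT_N_EPOCHS = 30


@dataclass
class RawRecording:
    """Continuous multichannel recording in microvolts.

    ``data`` is channels x samples; ``eog_channels`` names the ocular channels
    (a subset of ``labels``) that are excluded from the average reference and
    from amplitude rejection, and serve as regressors for ocular correction.
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    eog_channels: tuple[str, ...] = ()
    reference: str = "original"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = tuple(self.labels)
        self.eog_channels = tuple(self.eog_channels)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not set(self.eog_channels) <= set(self.labels):
            raise ValueError("eog_channels must be a subset of labels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def eeg_picks(self) -> np.ndarray:
        """Indices of non-EOG channels, in recording order."""
        eog = set(self.eog_channels)
        return np.array([i for i, l in enumerate(self.labels) if l not in eog], int)

    @property
    def eog_picks(self) -> np.ndarray:
        eog = set(self.eog_channels)
        return np.array([i for i, l in enumerate(self.labels) if l in eog], int)


@dataclass
class EpochSet:
    """Fixed-length epochs (epochs x channels x samples) with per-epoch status."""

    epochs: np.ndarray
    fs: float
    labels: tuple[str, ...]
    eog_channels: tuple[str, ...]
    epoch_len_s: float
    status: np.ndarray = field(default=None)

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = tuple(self.labels)
        self.eog_channels = tuple(self.eog_channels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be epochs x channels x samples")
        if self.status is None:
            self.status = np.full(self.epochs.shape[0], KEPT, dtype=object)
        self.status = np.asarray(self.status, dtype=object)
        if self.status.shape != (self.epochs.shape[0],):
            raise ValueError("one status per epoch required")
        bad = set(self.status) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown epoch statuses: {bad}")
        expected = int(round(self.epoch_len_s * self.fs))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} samples != "
                f"round(epoch_len_s * fs) = {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def eeg_picks(self) -> np.ndarray:
        eog = set(self.eog_channels)
        return np.array([i for i, l in enumerate(self.labels) if l not in eog], int)

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.status == KEPT)

    @property
    def kept_epochs(self) -> np.ndarray:
        """Kept epochs only, EEG channels only (epochs x channels x samples)."""
        return self.epochs[self.kept_indices][:, self.eeg_picks, :]

    def status_counts(self) -> dict[str, int]:
        return {s: int(np.sum(self.status == s)) for s in STATUSES}


def rereference_average(raw: RawRecording) -> RawRecording:
    """Subtract the instantaneous mean of the EEG channels from each EEG channel.

    EOG channels are excluded from the average and left untouched. The channel
    mean of the re-referenced EEG is zero at every sample.
    """
    if raw.reference == "average":
        raise ValueError("recording is already average-referenced")
    picks = raw.eeg_picks
    if len(picks) < 2:
        raise ValueError("average reference requires at least two EEG channels")
    data = raw.data.copy()
    data[picks] -= data[picks].mean(axis=0, keepdims=True)
    return replace(raw, data=data, reference="average")


def highpass(raw: RawRecording, cutoff: float = 1.0,
             order: int = spectral.DEFAULT_FILTER_ORDER) -> RawRecording:
    """Zero-phase Butterworth high-pass (order per pass) on every channel."""
    if not 0 < cutoff < raw.fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz outside (0, Nyquist={raw.fs / 2}) Hz")
    from scipy import signal

    sos = signal.butter(order, cutoff, btype="highpass", fs=raw.fs, output="sos")
    return replace(raw, data=signal.sosfiltfilt(sos, raw.data, axis=-1))


def regress_eog(raw: RawRecording) -> RawRecording:
    """Remove ocular activity from each EEG channel by least-squares regression.

    For each EEG channel the coefficients ``b`` solving the regression of the
    channel on all EOG channels (with an intercept) are estimated, and
    ``sum_k b_k * EOG_k`` is subtracted. On the fitted data every output EEG
    channel is exactly uncorrelated with every EOG regressor. Constant-zero
    EOG channels are skipped with a warning.
    """
    eog_idx = raw.eog_picks
    if len(eog_idx) == 0:
        raise ValueError("no EOG channels present")
    usable = []
    for i in eog_idx:
        if np.ptp(raw.data[i]) == 0:
            warnings.warn(
                f"EOG channel {raw.labels[i]!r} is constant; skipped as a regressor",
                stacklevel=2,
            )
        else:
            usable.append(i)
    if not usable:
        return replace(raw, data=raw.data.copy())
    eog = raw.data[usable]  # k x samples
    picks = raw.eeg_picks
    design = np.column_stack([np.ones(raw.n_samples), eog.T])  # n x (1+k)
    coef, *_ = np.linalg.lstsq(design, raw.data[picks].T, rcond=None)
    data = raw.data.copy()
    data[picks] -= coef[1:].T @ eog  # subtract only the EOG part, keep the mean
    return replace(raw, data=data)


def epoch(raw: RawRecording, epoch_len_s: float = DEFAULT_EPOCH_LEN_S) -> EpochSet:
    """Divide the recording into consecutive non-overlapping epochs from sample 0.

    The trailing partial segment is discarded; all statuses start ``kept``.
    """
    n_samp = int(round(epoch_len_s * raw.fs))
    n_ep = raw.n_samples // n_samp
    if n_ep < 1:
        raise ValueError(
            f"recording of {raw.n_samples} samples shorter than one "
            f"{epoch_len_s} s epoch ({n_samp} samples)"
        )
    cut = raw.data[:, : n_ep * n_samp]
    epochs = cut.reshape(cut.shape[0], n_ep, n_samp).transpose(1, 0, 2).copy()
    return EpochSet(epochs=epochs, fs=raw.fs, labels=raw.labels,
                    eog_channels=raw.eog_channels, epoch_len_s=epoch_len_s)


def reject_amplitude(es: EpochSet,
                     threshold: float = DEFAULT_AMPLITUDE_THRESHOLD_UV) -> EpochSet:
    """Reject kept epochs whose absolute amplitude exceeds ``threshold`` (uV)
    at any sample of any EEG channel (strict inequality)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    picks = es.eeg_picks
    status = es.status.copy()
    for i in es.kept_indices:
        if np.abs(es.epochs[i, picks]).max() > threshold:
            status[i] = REJECTED_AMPLITUDE
    return replace(es, epochs=es.epochs, status=status)


def drowsiness_ratio(es: EpochSet, epoch_index: int) -> float:
    """Theta/alpha power ratio of one epoch, channel-averaged.

    The PSD is averaged across EEG channels before integrating the theta
    (4-8 Hz) and alpha (8-12 Hz) bands; the relative-power denominator
    cancels in the ratio. Zero alpha power maps to ``inf``.
    """
    x = es.epochs[epoch_index, es.eeg_picks]
    freqs, psd = spectral.welch_psd(x, es.fs)
    mean_psd = psd.mean(axis=0)
    theta = spectral.integrate_band(freqs, mean_psd, *_band_edges("theta"))
    alpha = spectral.integrate_band(freqs, mean_psd, *_band_edges("alpha"))
    if alpha == 0:
        warnings.warn(
            f"epoch {epoch_index}: zero alpha power; drowsiness ratio set to inf",
            stacklevel=2,
        )
        return np.inf
    return float(theta / alpha)


def _band_edges(name: str) -> tuple[float, float]:
    b = spectral.BAND_MAP[name]
    return b.lo, b.hi


def reject_drowsy(es: EpochSet) -> EpochSet:
    """Reject kept epochs whose theta/alpha power ratio exceeds 1 (strict).

    Epochs with theta power dominating alpha are regarded as drowsiness or
    sleep-onset segments and excluded from resting-state analysis.
    """
    if es.fs <= 24:
        raise ValueError("sampling rate too low to resolve the alpha band")
    status = es.status.copy()
    kept = es.kept_indices
    if len(kept) == 0:
        return replace(es, epochs=es.epochs, status=status)
    x = es.epochs[kept][:, es.eeg_picks, :]
    freqs, psd = spectral.welch_psd(x, es.fs)
    mean_psd = psd.mean(axis=1)  # kept epochs x freqs
    theta = spectral.integrate_band(freqs, mean_psd, *_band_edges("theta"))
    alpha = spectral.integrate_band(freqs, mean_psd, *_band_edges("alpha"))
    zero_alpha = alpha == 0
    if np.any(zero_alpha):
        warnings.warn(
            f"{int(zero_alpha.sum())} epoch(s) with zero alpha power; "
            "drowsiness ratio treated as inf",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(zero_alpha, np.inf, theta / np.where(zero_alpha, 1, alpha))
    status[kept[ratio > 1]] = REJECTED_DROWSY
    return replace(es, epochs=es.epochs, status=status)


def select_epochs(es: EpochSet, n: int = DEFAULT_N_EPOCHS, subject=None) -> EpochSet:
    """Keep the first ``n`` surviving epochs in temporal order.

    Remaining kept epochs become ``not_selected``. Raises
    :class:`InsufficientEpochsError` (naming the subject) if fewer than ``n``
    epochs survived screening.
    """
    kept = es.kept_indices
    if len(kept) < n:
        raise InsufficientEpochsError(
            f"subject {subject!r}: only {len(kept)} artifact-free epochs "
            f"available, {n} required"
        )
    status = es.status.copy()
    status[kept[n:]] = NOT_SELECTED
    return replace(es, epochs=es.epochs, status=status)


def screen(raw: RawRecording, epoch_len_s: float = DEFAULT_EPOCH_LEN_S,
           amp_threshold: float = DEFAULT_AMPLITUDE_THRESHOLD_UV,
           n_epochs: int = DEFAULT_N_EPOCHS, highpass_hz: float = 1.0,
           subject=None) -> EpochSet:
    """Full screening chain from a continuous recording to the selected epochs."""
    r = raw if raw.reference == "average" else rereference_average(raw)
    r = highpass(r, highpass_hz)
    if r.eog_channels:
        r = regress_eog(r)
    es = epoch(r, epoch_len_s)
    es = reject_amplitude(es, amp_threshold)
    es = reject_drowsy(es)
    return select_epochs(es, n_epochs, subject=subject)
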