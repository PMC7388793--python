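"""Phase-locking-value (PLV) functional connectivity between node time series.

For band-limited signals the instantaneous phase is the argument of the
analytic signal (the signal plus *i* times its quadrature). For two phase
series of length *n*,

    PLV = | (1/n) sum_t exp( i (phi_i(t) - phi_j(t)) ) |

ranging from 0 (no consistent phase relation) to 1 (perfect locking). The
matrix estimator band-passes each node series within each epoch (zero-phase
Butterworth), extracts phases, discards a fraction of samples at each epoch
edge to suppress analytic-signal edge artifacts, computes all pairwise PLVs,
and averages the resulting matrices arithmetically across epochs. Zero-lag
phase differences are *not* excluded: with purely zero-phase coupling PLV is
maximal, which is the estimator's stated behaviour here.

PLV is invariant to per-node amplitude scaling and to a common time shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from . import spectral
from .spectral import BandDefinition

DEFAULT_EDGE_TRIM = 0.1  # fraction of samples discarded at each epoch edge


@dataclass
class ConnectivityMatrix:
    """Per-band symmetric node x node PLV matrix in [0, 1], zero diagonal."""

    band: BandDefinition
    W: np.ndarray
    n_epochs_averaged: int

    def __post_init__(self):
        self.W = np.asarray(self.W, float)
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise ValueError("W must be square")
        if not np.allclose(self.W, self.W.T, atol=1e-10):
            raise ValueError("W must be symmetric")
        if np.any(self.W < 0) or np.any(self.W > 1):
            raise ValueError("PLV weights must lie in [0, 1]")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


def instantaneous_phase(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Phase of the analytic signal, in (-pi, pi].

    ``x`` should be band-limited (e.g. the output of ``spectral.bandpass``);
    an all-zero input has no defined phase and raises.
    """
    x = np.asarray(x, float)
    if not np.any(x):
        raise ValueError("phase of an all-zero signal is undefined")
    return np.angle(signal.hilbert(x, axis=axis))


def plv(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """PLV of two phase series: magnitude of the mean unit phasor of their
    difference."""
    phase_i = np.asarray(phase_i, float)
    phase_j = np.asarray(phase_j, float)
    if phase_i.shape != phase_j.shape:
        raise ValueError("phase series must have equal length")
    if phase_i.size < 2:
        raise ValueError("need at least two samples")
    return float(np.abs(np.mean(np.exp(1j * (phase_i - phase_j)))))


def plv_matrix(node_epochs: np.ndarray, fs: float, band,
               trim_frac: float = DEFAULT_EDGE_TRIM) -> ConnectivityMatrix:
    """Epoch-averaged pairwise PLV matrix of node time series.

    ``node_epochs`` is kept epochs x nodes x samples. Per epoch, each node
    series is band-passed, its analytic phase extracted, ``trim_frac`` of
    samples dropped at each edge, and the full pairwise PLV matrix computed
    as ``|Z Z^H| / n`` with ``Z`` the unit-phasor matrix; matrices are then
    averaged over epochs. Phasor products are accumulated in single
    precision (the estimator's sampling noise dominates far earlier), the
    average in double.
    """
    band = spectral.get_band(band)
    x = np.asarray(node_epochs, float)
    if x.ndim != 3:
        raise ValueError("node_epochs must be epochs x nodes x samples")
    n_ep, n_nodes, n_samp = x.shape
    if n_ep < 1:
        raise ValueError("need at least one kept epoch")
    if not 0 <= trim_frac < 0.5:
        raise ValueError("trim_frac must lie in [0, 0.5)")
    silent = np.flatnonzero(~np.any(x, axis=(0, 2)))
    if len(silent) > 0:
        raise ValueError(f"node(s) {silent.tolist()} have all-zero time series")

    xf = spectral.bandpass(x, fs, band)
    analytic = signal.hilbert(xf, axis=-1)
    trim = int(round(trim_frac * n_samp))
    if trim > 0:
        analytic = analytic[..., trim:n_samp - trim]
    env = np.abs(analytic)
    dead = env.min(axis=-1) == 0
    if np.any(dead):
        nodes = sorted(set(np.where(dead)[1].tolist()))
        raise ValueError(
            f"node(s) {nodes} have vanishing band-limited amplitude in "
            f"band {band.name!r}; phase is undefined"
        )
    z = (analytic / env).astype(np.complex64)
    n = z.shape[-1]
    cross = np.abs(np.matmul(z, z.conj().transpose(0, 2, 1))) / n
    w = cross.mean(axis=0, dtype=np.float64)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(band=band, W=w, n_epochs_averaged=n_ep)
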