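"""Weighted graph indices on PLV connectivity matrices.

All measures operate on a symmetric nonnegative weight matrix ``W`` with zero
diagonal (PLV weights in [0, 1]); the network stays fully weighted — no
thresholding or binarization.

* **strength**: nodal ``s_i = sum_j w_ij``; the global value is the *mean*
  over nodes (so a complete graph of uniform weight ``w`` has global strength
  ``(N - 1) w``).
* **clustering coefficient** (Onnela geometric-mean convention): with
  ``w_hat = W / max(W)``,
  ``C_i = sum_{j != h} (w_hat_ij w_hat_ih w_hat_jh)^{1/3} / (k_i (k_i - 1))``
  where ``k_i`` counts node *i*'s nonzero links; ``C_i = 0`` for ``k_i < 2``.
  Global CC is the mean of nodal CCs.
* **path length / efficiency**: link lengths are reciprocal weights
  ``l_ij = 1 / w_ij`` (infinite for absent links); ``d_ij`` are shortest-path
  distances (Dijkstra). PL is the mean finite off-diagonal distance,
  efficiency the mean of ``1 / d_ij`` with ``1/inf = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import shortest_path


@dataclass
class NetworkIndices:
    """Global indices plus the nodal clustering profile for one subject/band."""

    strength: float
    cc: float
    pl: float
    efficiency: float
    nodal_cc: np.ndarray
    band: str | None = None
    subject: str | None = None

    def __post_init__(self):
        self.nodal_cc = np.asarray(self.nodal_cc, float)
        n = len(self.nodal_cc)
        checks = [
            0 <= self.strength <= n - 1 + 1e-9,
            0 <= self.cc <= 1 + 1e-9,
            0 <= self.efficiency <= 1 + 1e-9,
            np.all((self.nodal_cc >= 0) & (self.nodal_cc <= 1 + 1e-9)),
        ]
        if not all(checks):
            raise ValueError(
                f"network indices out of range for PLV weights: "
                f"strength={self.strength}, cc={self.cc}, "
                f"efficiency={self.efficiency}"
            )


def _validate(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    if np.any(W < 0):
        raise ValueError("W must be nonnegative")
    if np.any(np.diag(W) != 0):
        raise ValueError("W must have a zero diagonal")
    return W


def strength(W: np.ndarray) -> tuple[np.ndarray, float]:
    """Nodal strengths (row sums) and their across-node mean."""
    W = _validate(W)
    s = W.sum(axis=1)
    return s, float(s.mean())


def nodal_cc(W: np.ndarray) -> np.ndarray:
    """Weighted nodal clustering coefficients (Onnela, max-normalized)."""
    W = _validate(W)
    wmax = W.max()
    if wmax == 0:
        warnings.warn("all-zero weight matrix: clustering set to 0", stacklevel=2)
        return np.zeros(W.shape[0])
    a3 = np.cbrt(W / wmax)
    triangles = np.diagonal(a3 @ a3 @ a3)  # 2 x (geometric-mean triangle sum)
    k = np.count_nonzero(W, axis=1)
    denom = k * (k - 1)
    out = np.zeros(W.shape[0])
    ok = denom > 0
    out[ok] = triangles[ok] / denom[ok]
    return out


def global_cc(W: np.ndarray) -> float:
    """Mean of the nodal clustering coefficients."""
    return float(nodal_cc(W).mean())


def distances(W: np.ndarray) -> np.ndarray:
    """Pairwise shortest-path distances under reciprocal-weight link lengths.

    ``l_ij = 1 / w_ij`` where ``w_ij > 0``; absent links have infinite length.
    Disconnected pairs come back as ``inf``.
    """
    W = _validate(W)
    lengths = np.zeros_like(W)
    nz = W > 0
    lengths[nz] = 1.0 / W[nz]
    d = shortest_path(sparse.csr_matrix(lengths), method="D", directed=False)
    return d


def path_length_and_efficiency(d: np.ndarray) -> tuple[float, float]:
    """Characteristic path length and global efficiency from a distance matrix.

    PL averages finite off-diagonal distances; efficiency averages
    ``1 / d_ij`` over all off-diagonal pairs with ``1/inf = 0``.
    """
    d = np.asarray(d, float)
    off = ~np.eye(d.shape[0], dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any():
        raise ValueError("all pairwise distances are infinite")
    pl = float(d[finite].mean())
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    efficiency = float(inv[off].mean())
    return pl, efficiency


def network_indices(W: np.ndarray, band: str | None = None,
                    subject: str | None = None) -> NetworkIndices:
    """All global indices plus nodal clustering for one connectivity matrix."""
    W = _validate(W)
    _, glob_strength = strength(W)
    ncc = nodal_cc(W)
    pl, eff = path_length_and_efficiency(distances(W))
    return NetworkIndices(strength=glob_strength, cc=float(ncc.mean()), pl=pl,
                          efficiency=eff, nodal_cc=ncc, band=band,
                          subject=subject)
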