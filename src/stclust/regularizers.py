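"""Spatial penalties and proximal operators for subunit filters.

Two priors are supported inside the clustering loop: plain L1 (sparsity,
agnostic to spatial arrangement) and the locally normalized L1 (LNL1),
which penalizes a pixel only when its spatial neighbors are weak:

    L(k) = sum_i |k_i| / (eps + sum_{j in nbr(i)} |k_j|)

LNL1 therefore favors spatially contiguous filters while remaining
relatively insensitive to their area.  Both are applied through their
proximal operators after each cluster-centroid update; for LNL1 the
proximal operator of a first-order (majorize-minimize) approximation is
used, i.e. a weighted soft threshold with per-pixel weight
``a_i = 1/(eps + sum_{j in nbr(i)} |k_j|)`` computed from the
pre-update filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "NeighborhoodGraph",
    "grid_neighbors",
    "prox_l1",
    "l1_penalty",
    "lnl1_weights",
    "prox_lnl1",
    "lnl1_penalty",
    "make_regularizer",
]

#: Default local-normalization offset, small relative to typical
#: nonzero filter values (order unity).
DEFAULT_EPS = 0.01


@dataclass
class NeighborhoodGraph:
    """Pixel adjacency on a rectangular grid (no self-loops, symmetric)."""

    grid_shape: tuple[int, int]
    connectivity: int = 4
    adjacency: sparse.csr_matrix = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        rows, cols = self.grid_shape
        idx = np.arange(rows * cols).reshape(rows, cols)
        offsets = [(0, 1), (1, 0)]
        if self.connectivity == 8:
            offsets += [(1, 1), (1, -1)]
        src, dst = [], []
        for dr, dc in offsets:
            r0, r1 = max(0, -dr), rows - max(0, dr)
            c0, c1 = max(0, -dc), cols - max(0, dc)
            a = idx[r0:r1, c0:c1]
            b = idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
            src.append(a.ravel())
            dst.append(b.ravel())
        src = np.concatenate(src)
        dst = np.concatenate(dst)
        n = rows * cols
        adj = sparse.coo_matrix(
            (np.ones(src.size), (src, dst)), shape=(n, n))
        self.adjacency = (adj + adj.T).tocsr()

    @property
    def n_pixels(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency[i].indices


def grid_neighbors(grid_shape: tuple[int, int], connectivity: int = 4) -> NeighborhoodGraph:
    """Neighborhood graph of a rows x cols pixel grid."""
    return NeighborhoodGraph(grid_shape, connectivity)


def prox_l1(v: np.ndarray, lam: float) -> np.ndarray:
    """Soft-thresholding operator, the proximal map of lam*|.|_1."""
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    v = np.asarray(v, dtype=float)
    return np.maximum(v - lam, 0.0) - np.maximum(-v - lam, 0.0)


def l1_penalty(k: np.ndarray) -> float:
    return float(np.abs(k).sum())


def lnl1_weights(k: np.ndarray, eps: float = DEFAULT_EPS,
                 nbr: NeighborhoodGraph | None = None) -> np.ndarray:
    """Per-pixel LNL1 thresholds a_i = 1/(eps + sum_{j in nbr(i)} |k_j|)."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    if nbr is None:
        raise ValueError("a NeighborhoodGraph is required")
    k = np.asarray(k, dtype=float)
    return 1.0 / (eps + nbr.adjacency @ np.abs(k))


def prox_lnl1(k: np.ndarray, lam: float, eps: float = DEFAULT_EPS,
              nbr: NeighborhoodGraph | None = None,
              ref: np.ndarray | None = None) -> np.ndarray:
    """One majorize-minimize proximal step of the LNL1 penalty.

    Weighted soft threshold with per-pixel threshold ``a_i * lam``.
    The normalizing weights a_i are evaluated at the expansion point of
    the Taylor (majorization) step: ``ref`` when given — inside the
    clustering loop this is the pre-update filter from the previous
    iteration — otherwise the input ``k`` itself.  Isolated pixels face
    a threshold up to lam/eps and are suppressed; pixels with strong
    neighbors are barely shrunk.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    k = np.asarray(k, dtype=float)
    a = lnl1_weights(k if ref is None else ref, eps=eps, nbr=nbr)
    t = a * lam
    return np.maximum(k - t, 0.0) - np.maximum(-k - t, 0.0)


def lnl1_penalty(k: np.ndarray, eps: float = DEFAULT_EPS,
                 nbr: NeighborhoodGraph | None = None) -> float:
    """Locally normalized L1 penalty sum_i |k_i|/(eps + sum_nbr |k_j|)."""
    k = np.asarray(k, dtype=float)
    return float((np.abs(k) * lnl1_weights(k, eps=eps, nbr=nbr)).sum())


def make_regularizer(reg: str, lam: float, eps: float = DEFAULT_EPS,
                     grid_shape: tuple[int, int] | None = None,
                     connectivity: int = 4):
    """Build (prox, penalty) callables for the clustering loop.

    Parameters
    ----------
    reg
        One of ``"none"``, ``"l1"``, ``"lnl1"``.

    Returns
    -------
    prox : callable(k, ref=None) or None
        Applied to each filter after the centroid update; ``ref`` is
        the pre-update filter (the majorization expansion point, used
        by lnl1).
    penalty : callable
        Maps a filter to its penalty value (always defined; 0 for none).
    """
    if reg == "none" or lam == 0:
        return None, lambda k: 0.0
    if reg == "l1":
        return (lambda k, ref=None: prox_l1(k, lam)), l1_penalty
    if reg == "lnl1":
        if grid_shape is None:
            raise ValueError("lnl1 regularization needs grid_shape")
        nbr = grid_neighbors(grid_shape, connectivity)
        return (lambda k, ref=None: prox_lnl1(k, lam, eps=eps, nbr=nbr,
                                              ref=ref)), (
            lambda k: lnl1_penalty(k, eps=eps, nbr=nbr))
    raise ValueError(f"unknown regularizer {reg!r}")
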