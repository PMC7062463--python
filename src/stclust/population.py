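"""Joint subunit estimation for simultaneously recorded cells.

Nearby retinal ganglion cells sample overlapping regions of the bipolar
mosaic and therefore share subunits.  The population model keeps one
common bank of subunit filters K_n and gives each cell c its own
nonnegative weights w_{n,c} (zero meaning "not connected") and output
nonlinearity:

    lambda_{c,t} = g_c( sum_n w_{n,c} exp(K_n . X_t) )

Fitting clusters the spike-triggered stimuli of all cells with a common
set of centroids: per-cell responsibilities, pooled filter updates
(optionally through a proximal operator; the locally normalized L1
prior is the default for retinal data), and per-cell weight updates;
per-cell output nonlinearities are fit in a second stage.  With a
single cell the procedure reduces exactly to the single-cell algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import FitTrace, _fit_bank, _spike_frames, fit_output_nonlinearity
from .model import OutputNonlinearity, SubunitBank, expected_nll

__all__ = [
    "PopulationModel",
    "fit_population",
    "best_separate_combination",
    "sharing_fraction",
]


@dataclass
class PopulationModel:
    """Shared subunit bank with per-cell weights and nonlinearities."""

    K: np.ndarray                              # N x D shared filters
    W: np.ndarray                              # C x N per-cell weights
    nonlinearities: list[OutputNonlinearity] = field(default_factory=list)
    grid_shape: tuple[int, int] | None = None
    trace: FitTrace | None = None

    def __post_init__(self) -> None:
        if np.any(self.W < 0):
            raise ValueError("per-cell weights must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.W.shape[0]

    @property
    def n_subunits(self) -> int:
        return self.K.shape[0]

    def cell_bank(self, c: int) -> SubunitBank:
        return SubunitBank(self.K, self.W[c])

    def weak_subunits(self, c: int, frac: float = 0.01) -> np.ndarray:
        """Indices of poorly estimated subunits for display purposes.

        A subunit is marked weak for cell c when its strength is below
        ``frac`` of the cell's total strength.
        """
        s = self.cell_bank(c).strengths
        return np.nonzero(s < frac * s.sum())[0]


def fit_population(X, Y_list, n_subunits: int, lam: float = 0.0,
                   reg: str = "lnl1", eps: float = 0.01, grid_shape=None,
                   max_iter: int = 100, tol: float = 1e-6, seed=None,
                   fit_nonlinearities: bool = True) -> PopulationModel:
    """Jointly estimate a shared subunit bank for several cells.

    ``Y_list`` holds per-cell spike counts aligned to the common
    stimulus X (whose window should cover all cells' receptive fields).
    The filter update pools spike-triggered frames across cells; weight
    updates are per cell.  With ``C=1`` and the same seed this produces
    exactly the single-cell fit.
    """
    K, W, trace = _fit_bank(X, list(Y_list), n_subunits, lam=lam, reg=reg,
                            eps=eps, grid_shape=grid_shape, max_iter=max_iter,
                            tol=tol, seed=seed)
    model = PopulationModel(K=K, W=W, grid_shape=grid_shape, trace=trace)
    if fit_nonlinearities:
        for c, Y in enumerate(Y_list):
            fitted = fit_output_nonlinearity(X, Y, model.cell_bank(c),
                                             seed=seed)
            model.W[c] = fitted.bank.w
            model.nonlinearities.append(fitted.nonlinearity)
    return model


def best_separate_combination(ll_tables: list[dict[int, float]], budget: int):
    """Allocate a total subunit budget across separately fitted cells.

    ``ll_tables[c]`` maps a subunit count N to that cell's validation
    log-likelihood.  Dynamic programming over cells finds the exact
    allocation (one entry per cell, summing to at most ``budget``) that
    maximizes total validation log-likelihood.

    Returns
    -------
    allocation : list of chosen N per cell
    total_ll : the maximized summed log-likelihood
    """
    C = len(ll_tables)
    if C == 0:
        raise ValueError("no cells")
    if budget < C:
        raise ValueError("budget smaller than one subunit per cell")
    NEG = -np.inf
    # dp[b] = (best total ll using exactly the first c cells and b subunits)
    dp = {0: (0.0, [])}
    for table in ll_tables:
        if not table:
            raise ValueError("a cell has no fits")
        new = {}
        for b, (val, alloc) in dp.items():
            for n, ll in table.items():
                nb = b + n
                if nb > budget:
                    continue
                cand = (val + ll, alloc + [n])
                if nb not in new or cand[0] > new[nb][0]:
                    new[nb] = cand
        dp = new
        if not dp:
            raise ValueError("budget infeasible for the available fits")
    best_val, best_alloc = max(dp.values(), key=lambda v: v[0])
    return best_alloc, float(best_val)


def sharing_fraction(fits_per_cell, threshold_sd: float = 1.0,
                     within_cell: bool = False) -> float:
    """Fraction of nearest-neighbor subunit pairs closer than a Gaussian SD.

    For each subunit (a 2-D Gaussian fit), the nearest subunit of a
    *different* cell is found; the pair counts as shared when the
    center separation is below ``threshold_sd`` times the geometric
    mean of the two fits' SDs along the center-joining direction.  With
    ``within_cell=True`` the same statistic is computed for neighbors
    within the same cell, the baseline prediction from single-cell
    subunit spacing.
    """
    cells = [list(f) for f in fits_per_cell]
    if sum(len(c) > 0 for c in cells) < 2 and not within_cell:
        raise ValueError("need subunit fits for at least two cells")
    flat = [(ci, f) for ci, fs in enumerate(cells) for f in fs]
    n_close = 0
    n_total = 0
    for i, (ci, fi) in enumerate(flat):
        best = None
        for j, (cj, fj) in enumerate(flat):
            if i == j:
                continue
            if within_cell and cj != ci:
                continue
            if not within_cell and cj == ci:
                continue
            d = np.linalg.norm(np.asarray(fi.center) - np.asarray(fj.center))
            if best is None or d < best[0]:
                best = (d, fj)
        if best is None:
            continue
        d, fj = best
        if d == 0:
            n_close += 1
            n_total += 1
            continue
        u = (np.asarray(fj.center) - np.asarray(fi.center)) / d
        si = np.sqrt(u @ fi.covariance @ u)
        sj = np.sqrt(u @ fj.covariance @ u)
        n_total += 1
        if d < threshold_sd * np.sqrt(si * sj):
            n_close += 1
    if n_total == 0:
        return 0.0
    return n_close / n_total
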