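"""Model selection, prediction accuracy, and subunit-geometry analyses.

Covers the surrounding analysis machinery: train/validation/test
partitioning (test = contiguous final segment; train/validation split
at random), cross-validated selection of the subunit count N and
regularization strength lambda, PSTH computation and PSTH-based
prediction accuracy for repeated-trial data, and the geometric
characterizations of fitted subunits (2-D Gaussian fits, the
pixel-permutation compactness control, nearest-neighbor tiling
statistic, and stimulus/receptive-field angles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import pearsonr

from .clustering import fit_output_nonlinearity, fit_subunits
from .model import (SpikeCounts, StimulusMatrix, _counts, _frames,
                    firing_rate, generator_signal, nll, poisson_nll,
                    sample_spikes)

__all__ = [
    "Partition",
    "Gaussian2DFit",
    "make_partition",
    "select_model",
    "validation_ll",
    "psth",
    "psth_correlation",
    "response_structure",
    "gaussian2d_fit",
    "permutation_control",
    "tiling_statistic",
    "rf_stimulus_angle",
]


@dataclass
class Partition:
    """Disjoint train/validation/test bin indices covering a recording."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        total = np.concatenate([self.train, self.validation, self.test])
        if np.unique(total).size != total.size:
            raise ValueError("partition sets overlap")


def make_partition(T: int, test_frac: float = 0.1, val_frac: float = 0.1,
                   seed=None) -> Partition:
    """Contiguous final test segment; random train/validation split of the rest.

    ``val_frac`` is the fraction of the *non-test* bins used for
    validation (training gets the rest, i.e. the 90/10 split of the
    remaining recording).
    """
    if test_frac + val_frac >= 1 or test_frac < 0 or val_frac < 0:
        raise ValueError("invalid partition fractions")
    n_test = int(np.ceil(test_frac * T))
    if T - n_test < 2:
        raise ValueError("recording too short to partition")
    rng = np.random.default_rng(seed)
    rest = rng.permutation(T - n_test)
    n_val = int(round(val_frac * rest.size))
    return Partition(train=np.sort(rest[n_val:]),
                     validation=np.sort(rest[:n_val]),
                     test=np.arange(T - n_test, T))


def validation_ll(bank_or_model, X, Y, idx) -> float:
    """Per-bin log-likelihood of a fitted model on the index set idx.

    Accepts a SubunitBank (clustering-stage model: identity output
    nonlinearity, rates = generator signal) or a full SubunitModel.
    """
    frames = _frames(X)[idx]
    counts = _counts(Y)[idx]
    if hasattr(bank_or_model, "bank"):
        rates = firing_rate(bank_or_model, frames)
    else:
        rates = generator_signal(bank_or_model, frames)
    return -poisson_nll(rates, counts)


def select_model(X, Y, n_grid=range(1, 13), lam_grid=(0.0,), reg: str = "none",
                 repeats: int = 3, seed=None, grid_shape=None, eps: float = 0.01,
                 test_frac: float = 0.1, val_frac: float = 0.1,
                 fit_nonlinearity: bool = False, max_iter: int = 100,
                 tol: float = 1e-6):
    """Cross-validated choice of subunit count N and regularization lambda.

    For every (N, lambda) pair the validation log-likelihood is
    averaged over ``repeats`` fits with random train/validation splits
    and initializations (the contiguous test tail is never touched).
    The same ``repeats`` splits and initialization seeds are shared
    across all grid cells (common random numbers), so grid comparisons
    are paired and split-to-split variance cancels.  By default the
    validation likelihood is computed for the clustering-stage model
    (identity output nonlinearity, which the fitted g closely
    approximates); ``fit_nonlinearity=True`` refits g per candidate
    before scoring.

    Returns
    -------
    n_best, lam_best : the selected values
    table : dict mapping (N, lam) -> mean validation log-likelihood
    """
    n_grid = list(n_grid)
    lam_grid = list(lam_grid)
    if not n_grid or not lam_grid:
        raise ValueError("empty hyperparameter grid")
    frames = _frames(X)
    counts = _counts(Y)
    rng = np.random.default_rng(seed)
    T = frames.shape[0]
    split_seeds = rng.integers(2**31, size=repeats)
    init_seeds = rng.integers(2**31, size=repeats)
    parts = [make_partition(T, test_frac, val_frac, seed=int(s))
             for s in split_seeds]
    table: dict[tuple[int, float], float] = {}
    for n in n_grid:
        for lam in lam_grid:
            vals = []
            for part, init_seed in zip(parts, init_seeds):
                Xtr = frames[part.train]
                Ytr = counts[part.train]
                bank, _ = fit_subunits(Xtr, Ytr, n, lam=lam, reg=reg, eps=eps,
                                       grid_shape=grid_shape,
                                       seed=int(init_seed),
                                       max_iter=max_iter, tol=tol)
                scored = bank
                if fit_nonlinearity:
                    scored = fit_output_nonlinearity(Xtr, Ytr, bank,
                                                     seed=int(init_seed))
                vals.append(validation_ll(scored, frames, counts,
                                          part.validation))
            table[(n, lam)] = float(np.mean(vals))
    (n_best, lam_best) = max(table, key=table.get)
    return n_best, lam_best, table


def _smoothing_kernel(sigma_bins: float):
    half = max(1, int(np.ceil(4 * sigma_bins)))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sigma_bins) ** 2)
    return k / k.sum()


def psth(rasters: np.ndarray, sigma: float = 1.0 / 60.0,
         bin_width: float = 1.0 / 120.0) -> np.ndarray:
    """Trial-averaged firing rate with Gaussian smoothing.

    ``sigma`` is the smoothing SD in seconds (default 16.67 ms).  The
    kernel is truncated at 4 sigma and renormalized at the edges
    (normalized convolution), so total count is conserved in the
    interior.  Returns expected counts per bin.  ``sigma=0`` returns
    the raw trial mean.
    """
    rasters = np.atleast_2d(np.asarray(rasters, dtype=float))
    mean = rasters.mean(axis=0)
    if sigma <= 0:
        return mean
    k = _smoothing_kernel(sigma / bin_width)
    sm = np.convolve(mean, k, mode="same")
    norm = np.convolve(np.ones_like(mean), k, mode="same")
    return sm / norm


def psth_correlation(model, X, rasters: np.ndarray, seed=None,
                     sigma: float = 1.0 / 60.0,
                     bin_width: float = 1.0 / 120.0) -> float:
    """Pearson correlation between recorded and model-predicted PSTHs.

    The model PSTH is built from freshly simulated Poisson spike trains
    matching the recorded number of repeats (matched-trial rule), then
    both are smoothed identically.
    """
    rasters = np.atleast_2d(np.asarray(rasters))
    R, T = rasters.shape
    rates = firing_rate(model, X) if hasattr(model, "bank") else np.asarray(model)
    rng = np.random.default_rng(seed)
    sim = np.stack([sample_spikes(rates, seed=rng.integers(2**31)).counts
                    for _ in range(R)])
    p_data = psth(rasters, sigma=sigma, bin_width=bin_width)
    p_model = psth(sim, sigma=sigma, bin_width=bin_width)
    if p_data.std() == 0 or p_model.std() == 0:
        raise ValueError("zero-variance PSTH: correlation undefined")
    return float(pearsonr(p_data, p_model).statistic)


def response_structure(rasters: np.ndarray, sigma: float = 1.0 / 60.0,
                       bin_width: float = 1.0 / 120.0) -> float:
    """Temporal structure of the response: variance of the PSTH over time."""
    return float(np.var(psth(rasters, sigma=sigma, bin_width=bin_width)))


def response_structure_ratio(null_rasters: np.ndarray,
                             noise_rasters: np.ndarray,
                             sigma: float = 1.0 / 60.0,
                             bin_width: float = 1.0 / 120.0) -> float:
    """PSTH-variance ratio null / white noise.

    Near zero for a linear cell (its null stimulus removes all drive);
    substantially positive when subunit nonlinearities respond to
    stimulation orthogonal to the receptive field.
    """
    denom = response_structure(noise_rasters, sigma=sigma,
                               bin_width=bin_width)
    if denom == 0:
        raise ValueError("white-noise PSTH has zero variance")
    return response_structure(null_rasters, sigma=sigma,
                              bin_width=bin_width) / denom


def post_event_mask(event_times: np.ndarray, n_bins: int,
                    bin_width: float = 1.0 / 120.0,
                    window: float = 0.25) -> np.ndarray:
    """Boolean mask of bins within a window after each event.

    Utility for restricting analyses to post-saccade (or other
    post-event) epochs, e.g. the first 250 ms after each image jump of
    a jittered natural-image stimulus.
    """
    mask = np.zeros(n_bins, dtype=bool)
    n_window = int(np.ceil(window / bin_width))
    for t in np.atleast_1d(event_times):
        b = int(np.floor(t / bin_width))
        if b < n_bins:
            mask[max(b, 0): min(b + n_window, n_bins)] = True
    return mask


@dataclass
class Gaussian2DFit:
    """Least-squares 2-D Gaussian description of a subunit image."""

    center: tuple[float, float]          # (x, y) = (col, row)
    covariance: np.ndarray               # 2x2 SPD
    amplitude: float
    mse: float
    ok: bool = True

    def sd_along(self, u: np.ndarray) -> float:
        u = np.asarray(u, dtype=float)
        u = u / np.linalg.norm(u)
        return float(np.sqrt(u @ self.covariance @ u))


def gaussian2d_fit(image: np.ndarray, grid_shape=None) -> Gaussian2DFit:
    """Fit amp * exp(-0.5 (p-c)' Sigma^-1 (p-c)) to a max-normalized image.

    The image is normalized by its maximum weight over space before
    fitting; the covariance is kept symmetric positive definite via a
    Cholesky parameterization of the precision.  Degenerate (flat)
    images yield a flagged fit.
    """
    img = np.asarray(image, dtype=float)
    if grid_shape is not None:
        img = img.reshape(grid_shape)
    if img.ndim != 2:
        raise ValueError("image must be 2-D (or give grid_shape)")
    peak = img.max()
    if peak <= 0 or np.ptp(img) == 0:
        return Gaussian2DFit((np.nan, np.nan), np.eye(2), np.nan, np.nan, ok=False)
    z = img / peak
    rows, cols = img.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    pos = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    zf = z.ravel()
    wts = np.clip(zf, 0, None)
    if wts.sum() == 0:
        wts = np.ones_like(zf)
    c0 = (pos * wts[:, None]).sum(axis=0) / wts.sum()
    d = pos - c0
    cov0 = (wts[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / wts.sum()
    cov0 += 0.25 * np.eye(2)
    L0 = np.linalg.cholesky(np.linalg.inv(cov0))

    def unpack(theta):
        amp, cx, cy, l11, l21, l22 = theta
        L = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
        return amp, np.array([cx, cy]), L

    def resid(theta):
        amp, c, L = unpack(theta)
        q = (pos - c) @ L
        return amp * np.exp(-0.5 * (q**2).sum(axis=1)) - zf

    theta0 = np.array([1.0, c0[0], c0[1], np.log(L0[0, 0]), L0[1, 0],
                       np.log(L0[1, 1])])
    try:
        res = optimize.least_squares(resid, theta0, method="lm", max_nfev=2000)
    except Exception:
        return Gaussian2DFit((np.nan, np.nan), np.eye(2), np.nan, np.nan, ok=False)
    amp, c, L = unpack(res.x)
    prec = L @ L.T
    cov = np.linalg.inv(prec)
    cov = 0.5 * (cov + cov.T)
    mse = float(np.mean(resid(res.x) ** 2))
    return Gaussian2DFit((float(c[0]), float(c[1])), cov, float(amp), mse,
                         ok=bool(res.success))


def permutation_control(subunits: np.ndarray, n_perm: int, seed=None,
                        grid_shape=None):
    """Pixel-permutation null distribution for subunit compactness.

    For each permutation the filter values at every pixel are shuffled
    across the subunits of the cell (same pixel, permuted subunit
    identity); Gaussian fits to the permuted subunits give a null MSE
    distribution.  Each real subunit's MSE quantile within the null is
    returned; compact real subunits sit near quantile 0.

    Returns
    -------
    null_mse : (n_perm * N,) array
    quantiles : (N,) array, or NaN with a degenerate flag when the
        permutation is vacuous (identical subunits)
    degenerate : bool
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    S = np.atleast_2d(np.asarray(subunits, dtype=float))
    N, D = S.shape
    if N < 2:
        raise ValueError("need at least two subunits to permute")
    rng = np.random.default_rng(seed)
    degenerate = bool(np.allclose(S, S[0]))
    real_mse = np.array([gaussian2d_fit(S[n], grid_shape).mse for n in range(N)])
    null_mse = []
    for _ in range(n_perm):
        perm = S.copy()
        for d in range(D):
            perm[:, d] = S[rng.permutation(N), d]
        null_mse.extend(gaussian2d_fit(perm[n], grid_shape).mse
                        for n in range(N))
    null_mse = np.asarray(null_mse)
    if degenerate:
        return null_mse, np.full(N, np.nan), True
    quantiles = np.array([(null_mse < m).mean() for m in real_mse])
    return null_mse, quantiles, False


def tiling_statistic(fits: list[Gaussian2DFit]) -> np.ndarray:
    """Normalized nearest-neighbor distances between subunit Gaussians.

    For each subunit: distance to its nearest neighbor divided by the
    geometric mean of the two fits' SDs along the center-joining
    direction.  Values near ~1.5 indicate tiling with minimal gaps and
    modest overlap.
    """
    if len(fits) < 2:
        raise ValueError("need at least two Gaussian fits")
    centers = np.array([f.center for f in fits], dtype=float)
    out = np.empty(len(fits))
    for i, fi in enumerate(fits):
        d = np.linalg.norm(centers - centers[i], axis=1)
        d[i] = np.inf
        j = int(np.argmin(d))
        u = centers[j] - centers[i]
        dist = d[j]
        u = u / dist
        out[i] = dist / np.sqrt(fi.sd_along(u) * fits[j].sd_along(u))
    return out


def rf_stimulus_angle(X, rf: np.ndarray) -> np.ndarray:
    """Angle (degrees, 0-180) between each stimulus frame and an RF vector.

    Zero frames yield NaN.
    """
    frames = _frames(X)
    rf = np.asarray(rf, dtype=float)
    nr = np.linalg.norm(rf)
    if nr == 0:
        raise ValueError("receptive field vector is zero")
    nf = np.linalg.norm(frames, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = frames @ rf / (nf * nr)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang[nf == 0] = np.nan
    return ang
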