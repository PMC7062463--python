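"""Spike-triggered soft clustering: the core subunit estimator.

The estimator treats spike-triggered stimulus frames as data points to
be softly clustered; cluster centroids become the subunit filters.  It
descends the approximate (expected) negative log-likelihood of the LNLN
model by repeating three closed-form updates, each the exact minimizer
of a convex upper bound that is tight at the current parameters
(a majorize-minimize scheme, so the objective is non-increasing):

1. activations   alpha_{t,n} <- softmax_n( K_n . X_t + log w_n )
2. filters       K_n <- sum_t Y_t alpha_{t,n} X_t / sum_t Y_t alpha_{t,n}
                 (followed by a proximal step when regularized)
3. weights       w_n <- (sum_t Y_t alpha_{t,n} / T) * exp(-|K_n|^2 / 2)

A second stage then fits the output nonlinearity g and per-subunit
scales by maximizing the full Poisson likelihood with the filter
directions held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import logsumexp, softmax

from .model import (OutputNonlinearity, SubunitBank, SubunitModel,
                    _counts, _frames, expected_nll, nll)
from .regularizers import make_regularizer

__all__ = [
    "SoftAssignments",
    "FitTrace",
    "update_activations",
    "update_filters",
    "update_weights",
    "fit_subunits",
    "fit_output_nonlinearity",
    "sta_decomposition_residual",
]


@dataclass
class SoftAssignments:
    """Per-spike-frame cluster responsibilities (S x N, rows sum to 1)."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        if np.any(self.alpha < 0):
            raise ValueError("responsibilities must be nonnegative")
        if not np.allclose(self.alpha.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("responsibility rows must sum to 1")


@dataclass
class FitTrace:
    """Per-iteration record of a clustering fit."""

    objective: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    seed: int | None = None
    rescues: list[tuple[int, int]] = field(default_factory=list)  # (iter, subunit)

    @property
    def monotone(self) -> bool:
        """Whether the surrogate never increased by more than 1e-8."""
        obj = np.asarray(self.objective)
        if obj.size < 2:
            return True
        return bool(np.all(np.diff(obj) <= 1e-8 * np.maximum(1.0, np.abs(obj[:-1]))))


def update_activations(X_spike, bank: SubunitBank) -> SoftAssignments:
    """Softmax responsibilities over subunits for each spike-triggered frame.

    Computed with max subtraction for overflow safety; subunits with
    zero weight receive zero responsibility.
    """
    frames = _frames(X_spike)
    if np.all(bank.w == 0):
        raise ValueError("all subunit weights are zero")
    with np.errstate(divide="ignore"):
        logits = frames @ bank.K.T + np.log(bank.w)
    return SoftAssignments(softmax(logits, axis=1))


def update_filters(X_spike, y_spike, alpha, prox=None, rng=None,
                   rescue_log: list | None = None, iteration: int = 0) -> np.ndarray:
    """Responsibility-weighted mean of spike-triggered frames per subunit.

    If a subunit has (numerically) zero responsibility mass it is
    reinitialized from a random spike-triggered frame when ``rng`` is
    given (the event is appended to ``rescue_log``), otherwise an error
    is raised.  The proximal operator ``prox``, if given, is applied to
    each centroid.
    """
    frames = _frames(X_spike)
    counts = _counts(y_spike).astype(float)
    a = alpha.alpha if isinstance(alpha, SoftAssignments) else np.asarray(alpha)
    resp = counts[:, None] * a  # S x N
    mass = resp.sum(axis=0)
    K = np.zeros((a.shape[1], frames.shape[1]))
    ok = mass > 1e-300
    K[ok] = (resp[:, ok].T @ frames) / mass[ok, None]
    for n in np.nonzero(~ok)[0]:
        if rng is None:
            raise ValueError(f"subunit {n} has empty responsibility mass")
        K[n] = frames[rng.integers(frames.shape[0])]
        if rescue_log is not None:
            rescue_log.append((iteration, int(n)))
    if prox is not None:
        K = np.stack([prox(K[n]) for n in range(K.shape[0])])
    return K


def update_weights(y_spike, alpha, K: np.ndarray, n_bins: int) -> np.ndarray:
    """w_n = (sum_t Y_t alpha_{t,n} / T) * exp(-|K_n|^2 / 2)."""
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    counts = _counts(y_spike).astype(float)
    a = alpha.alpha if isinstance(alpha, SoftAssignments) else np.asarray(alpha)
    return (counts @ a) / n_bins * np.exp(-0.5 * np.einsum("nd,nd->n", K, K))


def _spike_frames(X, Y):
    frames = _frames(X)
    counts = _counts(Y)
    if frames.shape[0] != counts.shape[0]:
        raise ValueError("stimulus and spike counts must have equal length")
    idx = np.nonzero(counts > 0)[0]
    return frames[idx], counts[idx].astype(float), frames.shape[0]


def _init_bank(X_spike_all, y_all, n_bins, n_subunits, rng, init, _unused=None):
    """Default init: STA direction plus scaled Gaussian noise per subunit."""
    D = X_spike_all.shape[1]
    sta = (y_all @ X_spike_all) / y_all.sum()
    mean_rate = y_all.sum() / n_bins
    if init == "sta-noise":
        noise_sd = 0.1 * np.linalg.norm(sta) / np.sqrt(D)
        K = sta[None, :] + noise_sd * rng.standard_normal((n_subunits, D))
    elif init == "random":
        K = rng.standard_normal((n_subunits, D)) * (np.linalg.norm(sta) / np.sqrt(D))
    else:
        raise ValueError(f"unknown init {init!r}")
    w = np.full(n_subunits, mean_rate / n_subunits)
    return K, w


def _fit_bank(X, Y_list, n_subunits, *, lam=0.0, reg="none", eps=0.01,
              grid_shape=None, connectivity=4, max_iter=100, tol=1e-6,
              seed=None, init="sta-noise", init_bank=None, frozen=None):
    """Shared clustering loop over one or several cells.

    ``Y_list`` is a list of per-cell spike-count arrays aligned to X.
    With one cell this is exactly the single-cell algorithm; with
    several, the filters are shared and pooled over cells while the
    weights stay per cell.  ``frozen`` optionally marks subunit indices
    whose filters and weights are not updated.

    Returns (K, W, trace) with W of shape (C, N).
    """
    rng = np.random.default_rng(seed)
    if grid_shape is None and hasattr(X, "grid_shape"):
        grid_shape = X.grid_shape
    prox, penalty = make_regularizer(reg, lam, eps=eps, grid_shape=grid_shape,
                                     connectivity=connectivity)
    cells = [_spike_frames(X, Y) for Y in Y_list]
    n_bins = cells[0][2]
    C = len(cells)
    Xs_all = np.concatenate([c[0] for c in cells])
    y_all = np.concatenate([c[1] for c in cells])
    if y_all.size == 0:
        raise ValueError("no spikes: cannot fit subunits")
    if init_bank is not None:
        K = init_bank.K.copy()
        if hasattr(init_bank, "W"):
            W = init_bank.W.copy()
        else:
            W = np.tile(init_bank.w, (C, 1))
    else:
        K, _ = _init_bank(Xs_all, y_all, n_bins, n_subunits, rng, init, None)
        # per-cell mean rate divided evenly over subunits
        W = np.stack([np.full(n_subunits, yc.sum() / n_bins / n_subunits)
                      for _, yc, _ in cells])
    frozen = np.zeros(n_subunits, bool) if frozen is None else np.asarray(frozen, bool)
    trace = FitTrace(seed=seed)

    def objective():
        val = 0.0
        for c, (Xs, yc, _) in enumerate(cells):
            val += expected_nll(SubunitBank(K, W[c]), Xs, yc, n_bins)
        return val + lam * sum(penalty(K[n]) for n in range(n_subunits))

    prev = objective()
    trace.objective.append(prev)
    for it in range(max_iter):
        resp_num = np.zeros_like(K)
        resp_mass = np.zeros(n_subunits)
        alphas = []
        for c, (Xs, yc, _) in enumerate(cells):
            alpha = update_activations(Xs, SubunitBank(K, W[c])).alpha
            alphas.append(alpha)
            r = yc[:, None] * alpha
            resp_num += r.T @ Xs
            resp_mass += r.sum(axis=0)
        K_new = K.copy()
        ok = resp_mass > 1e-300
        K_new[ok & ~frozen] = (resp_num[ok & ~frozen]
                               / resp_mass[ok & ~frozen, None])
        for n in np.nonzero(~ok & ~frozen)[0]:
            K_new[n] = Xs_all[rng.integers(Xs_all.shape[0])]
            trace.rescues.append((it, int(n)))
        if prox is not None:
            for n in np.nonzero(~frozen)[0]:
                # lnl1 thresholds are evaluated at the pre-update filter
                K_new[n] = prox(K_new[n], ref=K[n])
        K = K_new
        for c, (Xs, yc, _) in enumerate(cells):
            w_new = update_weights(yc, alphas[c], K, n_bins)
            W[c, ~frozen] = w_new[~frozen]
        cur = objective()
        trace.objective.append(cur)
        trace.n_iter = it + 1
        if abs(prev - cur) < tol * max(abs(prev), 1e-12):
            trace.converged = True
            break
        prev = cur
    return K, W, trace


def fit_subunits(X, Y, n_subunits: int, lam: float = 0.0, reg: str = "none",
                 eps: float = 0.01, grid_shape=None, connectivity: int = 4,
                 max_iter: int = 100, tol: float = 1e-6, seed=None,
                 init: str = "sta-noise", init_bank: SubunitBank | None = None,
                 sort: bool = True) -> tuple[SubunitBank, FitTrace]:
    """Estimate a subunit bank by spike-triggered soft clustering.

    Alternates the three updates until the relative change of the
    surrogate objective (expected negative log-likelihood plus
    lam * penalty) drops below ``tol`` or ``max_iter`` is reached
    (fits typically converge in ~100 steps).  The returned bank is
    sorted by descending subunit strength.
    """
    if n_subunits < 1:
        raise ValueError("need at least one subunit")
    K, W, trace = _fit_bank(X, [Y], n_subunits, lam=lam, reg=reg, eps=eps,
                            grid_shape=grid_shape, connectivity=connectivity,
                            max_iter=max_iter, tol=tol, seed=seed, init=init,
                            init_bank=init_bank)
    bank = SubunitBank(K, W[0])
    if sort:
        bank = bank.sorted_by_strength()
    return bank, trace


def _softplus(x):
    return np.logaddexp(0.0, x)


def fit_output_nonlinearity(X, Y, bank: SubunitBank, seed=None,
                            n_starts: int = 3, refit: str = "scale"
                            ) -> SubunitModel:
    """Second estimation stage: fit g(x)=x^a/(1+bx) and subunit scales.

    Maximizes the full Poisson likelihood over per-subunit scales on the
    weights and the nonlinearity parameters (a > 0 via log, b >= 0 via
    softplus reparameterization), with the filter directions held
    fixed.  Deterministic given ``seed``; the best of ``n_starts``
    initializations is kept.  ``refit="scale"`` rescales each subunit's
    weight; ``refit="global"`` uses one common scale.
    """
    frames = _frames(X)
    counts = _counts(Y)
    N = bank.n_subunits
    n_scale = N if refit == "scale" else 1
    rng = np.random.default_rng(seed)
    proj = frames @ bank.K.T
    with np.errstate(divide="ignore"):
        logw0 = np.log(bank.w)
    spk = counts > 0
    y_spk = counts[spk].astype(float)
    T = frames.shape[0]

    def loss(theta):
        log_s = theta[:n_scale]
        a = np.exp(theta[n_scale])
        b = _softplus(theta[n_scale + 1])
        log_g = logsumexp(proj + logw0 + (log_s if n_scale == N else log_s[0]),
                          axis=1)
        log_rate = a * log_g - np.log1p(b * np.exp(np.minimum(log_g, 500)))
        rates = np.exp(np.minimum(log_rate, 500))
        return rates.sum() / T - (y_spk * log_rate[spk]).sum() / T

    best = None
    for s in range(n_starts):
        theta0 = np.zeros(n_scale + 2)
        # b starts at ~0.05: small, but with a usable softplus gradient
        theta0[n_scale + 1] = -3.0
        if s > 0:
            theta0[:n_scale] += 0.3 * rng.standard_normal(n_scale)
            theta0[n_scale] += 0.2 * rng.standard_normal()
            theta0[n_scale + 1] += 1.5 * rng.standard_normal()
        res = optimize.minimize(loss, theta0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    if not best.success:
        warnings.warn("output-nonlinearity optimizer did not fully converge; "
                      "returning best iterate", RuntimeWarning)
    theta = best.x
    log_s = theta[:n_scale]
    scales = np.exp(log_s if n_scale == N else np.full(N, log_s[0]))
    new_bank = SubunitBank(bank.K.copy(), bank.w * scales)
    nl = OutputNonlinearity(a=float(np.exp(theta[n_scale])),
                            b=float(_softplus(theta[n_scale + 1])))
    return SubunitModel(bank=new_bank, nonlinearity=nl)


def sta_decomposition_residual(bank: SubunitBank, X_spike, y_spike) -> float:
    """1 - cos(sum_n strength_n K_n, spike-triggered sum of frames).

    At an unregularized fixed point the strength-weighted sum of
    subunit filters is proportional to the STA, so the residual is near
    zero; proximal regularization breaks the identity.
    """
    frames = _frames(X_spike)
    counts = _counts(y_spike).astype(float)
    lhs = bank.strengths @ bank.K
    rhs = counts @ frames
    denom = np.linalg.norm(lhs) * np.linalg.norm(rhs)
    if denom == 0:
        return 2.0
    return float(1.0 - lhs @ rhs / denom)
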