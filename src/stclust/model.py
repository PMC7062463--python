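"""Core LNLN response model and its Poisson likelihood.

The model describes the instantaneous firing rate of a neuron as a
cascade of two linear-nonlinear stages:

    lambda_t = g( sum_n w_n * exp(K_n . X_t) )

where ``X_t`` is the (prefiltered, standardized) stimulus frame at bin t,
``K_n`` are spatial subunit filters, ``w_n >= 0`` are subunit weights and
``g(x) = x**a / (1 + b*x)`` is a saturating output nonlinearity
(identity for a=1, b=0).  Spikes are an inhomogeneous Poisson process
with per-bin rate ``lambda_t``; rates are expected counts per bin (the
bin width is absorbed into the weights).

For a standard-Gaussian stimulus the stimulus average of the generator
signal has a closed form via the Gaussian moment generating function,

    E[ sum_n w_n exp(K_n . X) ] = sum_n w_n exp(|K_n|^2 / 2),

which makes the approximate (expected) negative log-likelihood depend on
the stimulus only through spike-triggered frames; this is the objective
the clustering estimator minimizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "StimulusMatrix",
    "SpikeCounts",
    "SubunitBank",
    "OutputNonlinearity",
    "SubunitModel",
    "generator_signal",
    "firing_rate",
    "sample_spikes",
    "nll",
    "poisson_nll",
    "expected_nll",
    "subunit_strength",
]


@dataclass
class StimulusMatrix:
    """Prefiltered, standardized stimulus frames (T x D).

    Parameters
    ----------
    frames
        T x D array; rows are stimulus frames, columns pixels (or
        space-time bins for 1-D stimuli).
    bin_width
        Frame duration in seconds (default 1/120 s).
    grid_shape
        Optional (rows, cols) for reshaping filters to images.
    """

    frames: np.ndarray
    bin_width: float = 1.0 / 120.0
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2:
            raise ValueError("frames must be a T x D matrix")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("stimulus contains non-finite entries")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.frames.shape[1]

    def is_standardized(self, atol: float = 0.05) -> bool:
        """Check per-column mean ~ 0 and standard deviation ~ 1."""
        mu = self.frames.mean(axis=0)
        sd = self.frames.std(axis=0)
        return bool(np.all(np.abs(mu) <= atol) and np.all(np.abs(sd - 1.0) <= atol))


@dataclass
class SpikeCounts:
    """Binned spike counts aligned to stimulus frames."""

    counts: np.ndarray
    bin_width: float = 1.0 / 120.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SubunitBank:
    """A bank of N linear subunit filters with nonnegative weights.

    ``log w_n`` doubles as the hierarchical bias b_n used by the
    splitting estimator.
    """

    K: np.ndarray  # N x D
    w: np.ndarray  # N

    def __post_init__(self) -> None:
        self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float))
        if self.K.shape[0] != self.w.shape[0]:
            raise ValueError("K and w disagree on the number of subunits")
        if np.any(self.w < 0):
            raise ValueError("subunit weights must be nonnegative")
        if not np.all(np.isfinite(self.K)):
            raise ValueError("filters contain non-finite entries")

    @property
    def n_subunits(self) -> int:
        return self.K.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.K.shape[1]

    @property
    def strengths(self) -> np.ndarray:
        """Per-subunit average contribution to the rate, w_n exp(|K_n|^2/2)."""
        return self.w * np.exp(0.5 * np.einsum("nd,nd->n", self.K, self.K))

    def sorted_by_strength(self) -> "SubunitBank":
        order = np.argsort(self.strengths)[::-1]
        return SubunitBank(self.K[order].copy(), self.w[order].copy())


@dataclass
class OutputNonlinearity:
    """Saturating output nonlinearity g(x) = x**a / (1 + b*x), b >= 0."""

    a: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("exponent a must be positive")
        if self.b < 0:
            raise ValueError("saturation b must be nonnegative")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x**self.a / (1.0 + self.b * x)

    def log(self, log_x: np.ndarray) -> np.ndarray:
        """log g(exp(log_x)), numerically stable for small generator signals."""
        log_x = np.asarray(log_x, dtype=float)
        return self.a * log_x - np.log1p(self.b * np.exp(log_x))


@dataclass
class SubunitModel:
    """Full LNLN model: subunit bank, output nonlinearity and metadata."""

    bank: SubunitBank
    nonlinearity: OutputNonlinearity = field(default_factory=OutputNonlinearity)
    time_course: np.ndarray | None = None
    grid_shape: tuple[int, int] | None = None
    bin_width: float = 1.0 / 120.0

    def __post_init__(self) -> None:
        if self.grid_shape is not None:
            r, c = self.grid_shape
            if r * c != self.bank.n_pixels:
                raise ValueError("grid_shape inconsistent with filter length")


def _frames(X) -> np.ndarray:
    return X.frames if isinstance(X, StimulusMatrix) else np.asarray(X, dtype=float)


def _counts(Y) -> np.ndarray:
    return Y.counts if isinstance(Y, SpikeCounts) else np.asarray(Y)


def generator_signal(bank: SubunitBank, X) -> np.ndarray:
    """Generator signal G_t = sum_n w_n exp(K_n . X_t), length T."""
    frames = _frames(X)
    if frames.shape[1] != bank.n_pixels:
        raise ValueError(
            f"stimulus has {frames.shape[1]} pixels, bank expects {bank.n_pixels}"
        )
    return np.exp(log_generator_signal(bank, frames))


def log_generator_signal(bank: SubunitBank, X) -> np.ndarray:
    """log G_t via logsumexp; -inf where all weights vanish."""
    frames = _frames(X)
    proj = frames @ bank.K.T  # T x N
    with np.errstate(divide="ignore"):
        logw = np.log(bank.w)
    return logsumexp(proj + logw, axis=1)


def firing_rate(model: SubunitModel, X) -> np.ndarray:
    """Expected spike count per bin, lambda_t = g(G_t)."""
    return model.nonlinearity(generator_signal(model.bank, X))


def sample_spikes(rates: np.ndarray, seed=None, bin_width: float = 1.0 / 120.0) -> SpikeCounts:
    """Draw independent Poisson counts per bin; reproducible given seed."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    rng = np.random.default_rng(seed)
    return SpikeCounts(rng.poisson(rates), bin_width=bin_width)


def poisson_nll(rates: np.ndarray, Y) -> float:
    """Per-bin Poisson negative log-likelihood (1/T)[sum rate - sum Y log rate].

    The data-only log(Y!) constant is dropped, so values are comparable
    across models fit to the same data but not across datasets.
    """
    rates = np.asarray(rates, dtype=float)
    counts = _counts(Y)
    if rates.shape != counts.shape:
        raise ValueError("rates and counts must have equal length")
    spk = counts > 0
    if np.any(rates[spk] <= 0):
        raise FloatingPointError("zero rate at a bin with observed spikes")
    T = rates.shape[0]
    return float(rates.sum() / T - (counts[spk] * np.log(rates[spk])).sum() / T)


def nll(model: SubunitModel, X, Y) -> float:
    """Negative log-likelihood of the model (per bin, constants dropped)."""
    frames = _frames(X)
    counts = _counts(Y)
    if frames.shape[0] != counts.shape[0]:
        raise ValueError("stimulus and spike counts must have equal length")
    log_g = log_generator_signal(model.bank, frames)
    log_rate = model.nonlinearity.log(log_g)
    rates = np.exp(log_rate)
    spk = counts > 0
    if np.any(~np.isfinite(log_rate[spk])):
        raise FloatingPointError("zero rate at a bin with observed spikes")
    T = frames.shape[0]
    return float(rates.sum() / T - (counts[spk] * log_rate[spk]).sum() / T)


def expected_nll(bank: SubunitBank, X_spike, y_spike, n_bins: int) -> float:
    """Approximate negative log-likelihood for standard-Gaussian stimuli.

    The first (rate) term of the Poisson likelihood is replaced by its
    stimulus expectation sum_n w_n exp(|K_n|^2/2), so the objective
    depends on the stimulus only through the spike-triggered frames:

        sum_n w_n e^{|K_n|^2/2} - (1/T) sum_{t: Y_t>0} Y_t log G_t

    Parameters
    ----------
    X_spike, y_spike
        Frames and counts restricted to bins with at least one spike.
    n_bins
        Total number of stimulus bins T (not just spike bins).
    """
    frames = _frames(X_spike)
    counts = _counts(y_spike)
    rate_term = float(bank.strengths.sum())
    if counts.size == 0:
        return rate_term
    log_g = log_generator_signal(bank, frames)
    return rate_term - float((counts * log_g).sum()) / n_bins


def subunit_strength(k: np.ndarray, w: float) -> float:
    """Average contribution of one subunit to the rate: w * exp(k.k/2)."""
    if w < 0:
        raise ValueError("weight must be nonnegative")
    k = np.asarray(k, dtype=float)
    return float(w * np.exp(0.5 * k @ k))
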