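"""Ground-truth synthetic data: a two-layer retinal cascade and toy cells.

The biologically scaled simulator emulates a retinal ganglion cell
(RGC) receiving exponentiated inputs from 12 model bipolar cells, each
of which linearly sums a spatially localized group of the 64 cones of a
jittered hexagonal mosaic (nearest-neighbor spacing 5 grid units,
lattice oriented at 60 degrees to the stimulus grid).  Cones pool the
stimulus with a separable filter: Gaussian spatial profile (sd 1 g.u.)
and a shared biphasic temporal kernel.  Bipolar weights are positive
with 10% coefficient of variation, and a global output gain is
calibrated so the mean firing rate is ~19 spikes/s under the default
binary white noise.  Spikes are Poisson.

Low-dimensional toy LNLN cells (3 or 5 exponential subunits with known
filters) drive the parameter-recovery and consistency tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.special import ndtr
from sklearn.cluster import KMeans

from .model import (OutputNonlinearity, SpikeCounts, StimulusMatrix,
                    SubunitBank, generator_signal, sample_spikes)

__all__ = [
    "ConeMosaic",
    "RGCCell",
    "ToyCell",
    "biphasic_kernel",
    "make_mosaic",
    "assign_bipolars",
    "rgc_cell",
    "simulate_cell",
    "toy_cell",
    "white_noise",
    "gaussian_stimulus",
    "image_jitter_stimulus",
]


def biphasic_kernel(n_lags: int = 15, bin_width: float = 1.0 / 120.0,
                    peak: float = 0.05, trough: float = 0.08,
                    undershoot: float = 0.45) -> np.ndarray:
    """Biphasic temporal filter (difference of gamma bumps), unit l2 norm.

    Defaults give a parasol-like time course: positive peak near 50 ms,
    undershoot near 80 ms, ~125 ms total support at 120 Hz.
    """
    t = (np.arange(n_lags) + 0.5) * bin_width
    def bump(loc, shape=5.0):
        theta = loc / (shape - 1)
        g = t ** (shape - 1) * np.exp(-t / theta)
        return g / g.max()
    k = bump(peak) - undershoot * bump(trough, shape=6.0)
    return k / np.linalg.norm(k)


@dataclass
class ConeMosaic:
    """Cone (photoreceptor) positions with their common pooling filters."""

    positions: np.ndarray                 # n x 2, grid units
    spatial_sd: float = 1.0               # g.u.
    temporal: np.ndarray = field(default_factory=biphasic_kernel)

    @property
    def n_cones(self) -> int:
        return self.positions.shape[0]


def make_mosaic(n: int = 64, spacing: float = 5.0, angle_deg: float = 60.0,
                jitter_sd: float = 0.35, seed=None) -> ConeMosaic:
    """Jittered hexagonal cone lattice rotated relative to the stimulus grid."""
    side = int(round(np.sqrt(n)))
    if side * side != n:
        raise ValueError("n must be a square hex patch (e.g. 64)")
    rng = np.random.default_rng(seed)
    ii, jj = np.mgrid[0:side, 0:side]
    x = jj * spacing + (ii % 2) * spacing / 2.0
    y = ii * spacing * np.sqrt(3.0) / 2.0
    pos = np.column_stack([x.ravel(), y.ravel()]).astype(float)
    pos -= pos.mean(axis=0)
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    pos = pos @ rot.T
    pos += jitter_sd * rng.standard_normal(pos.shape)
    return ConeMosaic(pos)


def assign_bipolars(mosaic: ConeMosaic, k: int = 12, seed=None) -> np.ndarray:
    """Partition cones into k bipolar groups by k-means on their locations."""
    if k > mosaic.n_cones:
        raise ValueError("more bipolar cells than cones")
    seed = int(np.random.default_rng(seed).integers(2**31)) if not isinstance(seed, (int, np.integer)) else int(seed)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31))
    return km.fit_predict(mosaic.positions)


def _pixel_grid(n_pixels: int, pixel_size: float) -> np.ndarray:
    """Pixel edge coordinates of an n x n grid centered on the origin."""
    half = n_pixels * pixel_size / 2.0
    return np.linspace(-half, half, n_pixels + 1)


def _pooling_matrix(positions: np.ndarray, sd: float, edges: np.ndarray) -> np.ndarray:
    """Integral of each cone's spatial Gaussian over each stimulus pixel."""
    def cdf_diff(centers):
        z = (edges[None, :] - centers[:, None]) / sd
        c = ndtr(z)
        return c[:, 1:] - c[:, :-1]       # n_cones x n_pixels_1d
    wx = cdf_diff(positions[:, 0])
    wy = cdf_diff(positions[:, 1])
    # image convention: row = y, col = x, row-major flattening
    return (wy[:, :, None] * wx[:, None, :]).reshape(positions.shape[0], -1)


@dataclass
class RGCCell:
    """Ground-truth cone -> bipolar -> RGC cascade on a pixel grid."""

    mosaic: ConeMosaic
    labels: np.ndarray                    # cone -> bipolar assignment
    bipolar_weights: np.ndarray           # positive, CV ~ 10%
    input_gain: float
    output_gain: float
    pooling: np.ndarray                   # n_cones x D
    grid_shape: tuple[int, int]
    pixel_size: float
    bin_width: float = 1.0 / 120.0

    @property
    def n_bipolars(self) -> int:
        return self.bipolar_weights.shape[0]

    @property
    def true_subunits(self) -> np.ndarray:
        """Bipolar pooling maps projected onto stimulus pixels (k x D)."""
        k = self.n_bipolars
        maps = np.zeros((k, self.pooling.shape[1]))
        for b in range(k):
            maps[b] = self.pooling[self.labels == b].sum(axis=0)
        return maps

    def rates(self, raw: np.ndarray) -> np.ndarray:
        """Deterministic firing rate (expected counts/bin) for raw frames."""
        drive = raw @ self.pooling.T                       # T x n_cones
        drive = signal.lfilter(self.mosaic.temporal, [1.0], drive, axis=0)
        k = self.n_bipolars
        u = np.zeros((raw.shape[0], k))
        for b in range(k):
            u[:, b] = drive[:, self.labels == b].sum(axis=1)
        act = np.exp(self.input_gain * u)
        return self.output_gain * (act @ self.bipolar_weights)


def rgc_cell(seed=None, n_pixels: int = 12, pixel_size: float = 6.0,
             n_cones: int = 64, spacing: float = 5.0, jitter_sd: float = 0.35,
             n_bipolars: int = 12, weight_cv: float = 0.1,
             contrast: float = 0.48, target_rate: float = 19.0,
             bin_width: float = 1.0 / 120.0,
             calibration_minutes: float = 1.0) -> RGCCell:
    """Build and calibrate the default 64-cone / 12-bipolar model RGC.

    The bipolar input gain is set analytically so bipolar log-activations
    have unit variance under white noise of the given contrast, and the
    global output gain is calibrated on an internal white-noise run so
    the mean rate is ``target_rate`` spikes/s.
    """
    rng = np.random.default_rng(seed)
    mosaic = make_mosaic(n=n_cones, spacing=spacing, jitter_sd=jitter_sd,
                         seed=rng.integers(2**31))
    labels = assign_bipolars(mosaic, k=n_bipolars, seed=int(rng.integers(2**31)))
    w = 1.0 + weight_cv * rng.standard_normal(n_bipolars)
    w = np.abs(w)  # truncate at zero (CV 10%: negative draws ~ never)
    edges = _pixel_grid(n_pixels, pixel_size)
    pooling = _pooling_matrix(mosaic.positions, mosaic.spatial_sd, edges)
    # unit log-variance of bipolar inputs under iid pixel noise, sd contrast/2
    q_norms = np.array([np.linalg.norm(pooling[labels == b].sum(axis=0))
                        for b in range(n_bipolars)])
    sigma_px = contrast / 2.0
    input_gain = 1.0 / (sigma_px * np.median(q_norms))
    cell = RGCCell(mosaic=mosaic, labels=labels, bipolar_weights=w,
                   input_gain=input_gain, output_gain=1.0, pooling=pooling,
                   grid_shape=(n_pixels, n_pixels), pixel_size=pixel_size,
                   bin_width=bin_width)
    T_cal = int(round(calibration_minutes * 60.0 / bin_width))
    cal = white_noise(T_cal, (n_pixels, n_pixels), contrast=contrast,
                      seed=rng.integers(2**31))
    cell.output_gain = target_rate * bin_width / cell.rates(cal).mean()
    return cell


def simulate_cell(cell: RGCCell, raw: np.ndarray, seed=None
                  ) -> tuple[np.ndarray, SpikeCounts]:
    """Rates and Poisson spike counts of the model RGC for raw frames."""
    rates = cell.rates(np.asarray(raw, dtype=float))
    return rates, sample_spikes(rates, seed=seed, bin_width=cell.bin_width)


@dataclass
class ToyCell:
    """Explicit low-dimensional LNLN cell with known subunit filters."""

    bank: SubunitBank
    gain: float = 1.0
    nonlinearity: OutputNonlinearity = field(default_factory=OutputNonlinearity)
    grid_shape: tuple[int, int] | None = None

    @property
    def filters(self) -> np.ndarray:
        return self.bank.K

    def rates(self, X) -> np.ndarray:
        return self.gain * self.nonlinearity(generator_signal(self.bank, X))

    def responses(self, X, seed=None) -> SpikeCounts:
        return sample_spikes(self.rates(X), seed=seed)


def toy_cell(n_subunits: int = 3, dims=(4, 4), seed=None,
             filter_norm: float = 1.0, mean_rate: float = 0.12,
             nonlinearity: OutputNonlinearity | None = None) -> ToyCell:
    """Toy LNLN cell with known ground truth for recovery tests.

    ``dims=2`` builds unit-norm 2-D filters at distinct angles; a
    (rows, cols) grid builds spatially localized Gaussian-bump filters
    at well separated centers.  ``mean_rate`` is the target expected
    spike count per bin under a standard-Gaussian stimulus; with the
    default identity output nonlinearity the gain is set in closed form
    from the Gaussian moment generating function.
    """
    rng = np.random.default_rng(seed)
    if dims == 2 or dims == (2,):
        angles = np.pi * (np.arange(n_subunits) / n_subunits) + rng.uniform(0, 0.3)
        K = filter_norm * np.column_stack([np.cos(angles), np.sin(angles)])
        grid_shape = None
    else:
        rows, cols = dims
        yy, xx = np.mgrid[0:rows, 0:cols]
        # centers spread on a ring around the grid middle
        cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
        radius = 0.55 * min(rows, cols) / 2.0 + 0.4
        phis = 2 * np.pi * np.arange(n_subunits) / n_subunits + rng.uniform(0, 2 * np.pi)
        K = np.zeros((n_subunits, rows * cols))
        for n in range(n_subunits):
            c = (cy + radius * np.sin(phis[n]), cx + radius * np.cos(phis[n]))
            bump = np.exp(-((yy - c[0]) ** 2 + (xx - c[1]) ** 2) / (2 * 0.7**2))
            K[n] = filter_norm * bump.ravel() / np.linalg.norm(bump)
        grid_shape = (rows, cols)
    w = np.full(n_subunits, 1.0 / n_subunits)
    bank = SubunitBank(K, w)
    nl = nonlinearity or OutputNonlinearity()
    cell = ToyCell(bank=bank, gain=1.0, nonlinearity=nl, grid_shape=grid_shape)
    if nl.a == 1.0 and nl.b == 0.0:
        cell.gain = mean_rate / float(bank.strengths.sum())
    else:
        X_cal = gaussian_stimulus(20000, K.shape[1], seed=rng.integers(2**31))
        cell.gain = mean_rate / cell.rates(X_cal).mean()
    return cell


def white_noise(T: int, grid_shape, contrast: float = 0.48,
                binary: bool = True, seed=None) -> np.ndarray:
    """Raw white-noise frames (T x D): binary +-contrast/2 or Gaussian."""
    if not 0 < contrast <= 1:
        raise ValueError("contrast must be in (0, 1]")
    rng = np.random.default_rng(seed)
    D = int(np.prod(grid_shape)) if np.ndim(grid_shape) else int(grid_shape)
    half = contrast / 2.0
    if binary:
        return half * (2.0 * rng.integers(0, 2, size=(T, D)) - 1.0)
    return half * rng.standard_normal((T, D))


def image_jitter_stimulus(image: np.ndarray, offsets: np.ndarray,
                          grid_shape: tuple[int, int],
                          origin: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Crop a user-supplied image at jittered offsets (eye-movement hook).

    ``offsets`` is a T x 2 integer array of (row, col) displacements per
    frame (e.g. a fixational eye-movement trajectory); each frame is the
    ``grid_shape`` crop of ``image`` at ``origin + offset``.  No images
    are bundled; the caller provides them.  Frames are returned flat
    (T x D), mean-centered to the image mean.
    """
    image = np.asarray(image, dtype=float)
    offsets = np.asarray(offsets, dtype=int)
    rows, cols = grid_shape
    frames = np.empty((offsets.shape[0], rows * cols))
    for t, (dr, dc) in enumerate(offsets):
        r0, c0 = origin[0] + dr, origin[1] + dc
        if not (0 <= r0 and r0 + rows <= image.shape[0]
                and 0 <= c0 and c0 + cols <= image.shape[1]):
            raise ValueError(f"frame {t}: crop outside the image")
        frames[t] = image[r0:r0 + rows, c0:c0 + cols].ravel()
    return frames - image.mean()


def gaussian_stimulus(T: int, dims, seed=None,
                      bin_width: float = 1.0 / 120.0) -> StimulusMatrix:
    """Standard-Gaussian stimulus matrix (already standardized)."""
    rng = np.random.default_rng(seed)
    if np.ndim(dims):
        grid_shape = tuple(dims)
        D = int(np.prod(dims))
    else:
        grid_shape, D = None, int(dims)
    return StimulusMatrix(rng.standard_normal((T, D)), bin_width=bin_width,
                          grid_shape=grid_shape)
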