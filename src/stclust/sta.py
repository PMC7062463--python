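"""Spike-triggered-average utilities.

Converts raw stimulus movies into the standardized spatial stimulus the
subunit estimator consumes: STA computation, receptive-field masking and
cropping, common time-course extraction, temporal prefiltering and
per-pixel standardization, and the space-time separable approximation
used for null-stimulus construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .model import SpikeCounts, StimulusMatrix, _counts

__all__ = [
    "SpatioTemporalSTA",
    "compute_sta",
    "receptive_field_mask",
    "time_course",
    "prefilter_and_standardize",
    "separable_approx",
    "preprocess_recording",
]

#: MAD -> standard-deviation consistency factor for Gaussian noise.
_MAD_SCALE = 1.4826


@dataclass
class SpatioTemporalSTA:
    """Spike-triggered average: pixels x lag bins, most recent lag first."""

    values: np.ndarray  # D x L
    lag_bin: float = 1.0 / 120.0
    grid_shape: tuple[int, int] | None = None

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_lags(self) -> int:
        return self.values.shape[1]

    @property
    def spatial_peak(self) -> np.ndarray:
        """Spatial map at the lag of maximum energy."""
        lag = int(np.argmax((self.values**2).sum(axis=0)))
        return self.values[:, lag]


def compute_sta(raw: np.ndarray, Y, n_lags: int = 15,
                lag_bin: float = 1.0 / 120.0,
                grid_shape: tuple[int, int] | None = None) -> SpatioTemporalSTA:
    """Spike-count-weighted average of the stimulus preceding spikes.

    ``STA[d, l] = sum_t Y_t raw[t-l, d] / sum_t Y_t`` with zero padding
    for lags reaching before the start of the recording.  Lag 0 is the
    frame concurrent with the spike bin.
    """
    raw = np.asarray(raw, dtype=float)
    counts = _counts(Y).astype(float)
    if raw.shape[0] != counts.shape[0]:
        raise ValueError("stimulus and spike counts must have equal length")
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot compute an STA with zero total spikes")
    T, D = raw.shape
    sta = np.empty((D, n_lags))
    for lag in range(n_lags):
        sta[:, lag] = counts[lag:] @ raw[: T - lag if lag else T] / total
    return SpatioTemporalSTA(sta, lag_bin=lag_bin, grid_shape=grid_shape)


def receptive_field_mask(sta_spatial: np.ndarray, grid_shape: tuple[int, int],
                         k: float = 2.5, connectivity: int = 4):
    """Significant-pixel mask of a spatial STA map plus its crop window.

    The background noise level sigma is estimated robustly (median
    absolute deviation over all pixels, scaled for Gaussian
    consistency); the mask is the largest connected component of pixels
    with |value| > k*sigma, and the crop is its bounding rectangle
    extended by a one-pixel border (clipped at the grid edge).

    Returns
    -------
    mask : boolean array of grid_shape
    crop : (row_slice, col_slice)
    """
    if k <= 0:
        raise ValueError("threshold multiple k must be positive")
    img = np.asarray(sta_spatial, dtype=float).reshape(grid_shape)
    sigma = _MAD_SCALE * np.median(np.abs(img - np.median(img)))
    if sigma == 0:
        sigma = img.std()
    above = np.abs(img) > k * sigma
    if not above.any():
        raise ValueError("no receptive field: no pixel exceeds the threshold")
    structure = (ndimage.generate_binary_structure(2, 1) if connectivity == 4
                 else ndimage.generate_binary_structure(2, 2))
    labels, n = ndimage.label(above, structure=structure)
    sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    rows, cols = np.nonzero(mask)
    r0, r1 = max(int(rows.min()) - 1, 0), min(int(rows.max()) + 2, grid_shape[0])
    c0, c1 = max(int(cols.min()) - 1, 0), min(int(cols.max()) + 2, grid_shape[1])
    return mask, (slice(r0, r1), slice(c0, c1))


def time_course(sta: SpatioTemporalSTA, mask: np.ndarray) -> np.ndarray:
    """Common temporal filter: sign-aligned average over masked pixels.

    Each significant pixel's lag trace is multiplied by the sign of its
    peak before averaging, so ON- and OFF-dominated pixels reinforce
    rather than cancel; the result has unit l2 norm.
    """
    flat = np.asarray(mask).reshape(-1)
    if not flat.any():
        raise ValueError("mask selects no pixels")
    traces = sta.values[flat]  # M x L
    peaks = traces[np.arange(traces.shape[0]),
                   np.argmax(np.abs(traces), axis=1)]
    tc = (np.sign(peaks)[:, None] * traces).mean(axis=0)
    return tc / np.linalg.norm(tc)


def prefilter_and_standardize(raw: np.ndarray, tc: np.ndarray,
                              bin_width: float = 1.0 / 120.0,
                              grid_shape: tuple[int, int] | None = None) -> StimulusMatrix:
    """Temporally filter raw frames with tc, then standardize each pixel.

    ``X_t[d] = sum_l tc[l] * raw[t-l, d]`` (causal, zero-padded start),
    then each column is centered and scaled to unit variance so the
    estimator's standard-Gaussian stimulus assumption holds for binary
    or Gaussian white noise.
    """
    raw = np.asarray(raw, dtype=float)
    tc = np.asarray(tc, dtype=float)
    if tc.shape[0] > raw.shape[0]:
        raise ValueError("time course longer than the recording")
    filt = signal.lfilter(tc, [1.0], raw, axis=0)
    sd = filt.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance pixel after prefiltering (constant input?)")
    frames = (filt - filt.mean(axis=0)) / sd
    return StimulusMatrix(frames, bin_width=bin_width, grid_shape=grid_shape)


def preprocess_recording(raw: np.ndarray, Y, grid_shape: tuple[int, int],
                         n_lags: int = 15, threshold: float = 2.5,
                         bin_width: float = 1.0 / 120.0):
    """STA -> RF mask -> crop -> time course -> prefiltered stimulus.

    The standard pipeline that turns a raw white-noise movie and spike
    counts into the cropped, temporally prefiltered and standardized
    StimulusMatrix the subunit estimator consumes.

    Returns
    -------
    X : StimulusMatrix restricted to the cropped RF window
    info : dict with keys ``sta``, ``mask``, ``crop``, ``time_course``
    """
    raw = np.asarray(raw, dtype=float)
    sta = compute_sta(raw, Y, n_lags=n_lags, lag_bin=bin_width,
                      grid_shape=grid_shape)
    # mask on the rank-1 spatial factor: pools SNR coherently across lags
    spatial, _ = separable_approx(sta)
    mask, crop = receptive_field_mask(spatial, grid_shape, k=threshold)
    tc = time_course(sta, mask)
    window = np.zeros(grid_shape, dtype=bool)
    window[crop] = True
    X = prefilter_and_standardize(raw[:, window.ravel()], tc,
                                  bin_width=bin_width)
    X.grid_shape = (int(crop[0].stop - crop[0].start),
                    int(crop[1].stop - crop[1].start))
    return X, {"sta": sta, "mask": mask, "crop": crop, "time_course": tc,
               "window": window}


def separable_approx(sta: SpatioTemporalSTA) -> tuple[np.ndarray, np.ndarray]:
    """Best rank-1 (space x time) factorization of the STA.

    Returns (spatial, temporal) minimizing the Frobenius error of
    ``spatial @ temporal.T``.  Sign convention: the dominant spatial
    pixel is positive, so the temporal factor's peak carries the cell's
    ON (positive) or OFF (negative) polarity.
    """
    U, s, Vt = np.linalg.svd(sta.values, full_matrices=False)
    spatial = U[:, 0] * s[0]
    temporal = Vt[0]
    if spatial[np.argmax(np.abs(spatial))] < 0:
        spatial, temporal = -spatial, -temporal
    return spatial, temporal
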