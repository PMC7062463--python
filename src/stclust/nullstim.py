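"""Receptive-field null stimuli.

A null stimulus is the closest modification of a white-noise movie that
is orthogonal to the linear receptive fields of a set of cells: a
purely linear (LN) model of any of those cells is silent on it, so any
residual response modulation exposes nonlinear subunit structure.

Spatial nulling projects every frame onto the null space of the RF
matrix A (columns = vectorized spatial receptive fields):

    S_n = (I - A (A^T A)^-1 A^T) S_w

Spatio-temporal nulling handles full space-time filters by moving to
the temporal frequency domain, where the convolution constraints
decouple: at each frequency the complex spatial vector is projected
onto the null space of the filters' transforms.  For space-time
separable filters both constructions coincide.

Display constraints (pixel range and per-pixel temporal variance) are
enforced with Dykstra's alternating projection algorithm.  The variance
set is a sphere (non-convex), outside the classical convergence theory;
convergence is monitored and residuals are reported.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "spatial_null",
    "spectral_null",
    "enforce_constraints",
    "quantize_8bit",
]


def _projector(A: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto null(A^T); errors if A is rank-deficient."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.ndim != 2:
        raise ValueError("A must be D x C")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise np.linalg.LinAlgError("receptive-field matrix is rank-deficient")
    return np.eye(A.shape[0]) - A @ np.linalg.solve(A.T @ A, A.T)


def spatial_null(S_w: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Project each frame of S_w (T x D) onto the null space of A^T.

    Minimal l2 distortion: among all stimuli orthogonal to every RF in
    A, the result is the closest to the input frame by frame.
    """
    S_w = np.asarray(S_w, dtype=float)
    if S_w.ndim == 1:
        S_w = S_w[None, :]
    A2 = np.atleast_2d(np.asarray(A, dtype=float))
    if A2.shape[0] != S_w.shape[1]:
        A2 = A2.T
    P = _projector(A2)
    return S_w @ P.T


def spectral_null(S_w: np.ndarray, filters: np.ndarray,
                  atol: float = 1e-12) -> np.ndarray:
    """Null a movie against full spatio-temporal filters.

    Parameters
    ----------
    S_w
        T x D movie.
    filters
        C x D x L array (or D x L for one cell) of space-time filters;
        the defining constraint is that the circular convolution of the
        output with every filter, summed over pixels, vanishes at all
        times.

    At each discrete temporal frequency the complex spatial frame is
    projected onto the null space of the filters' transforms; columns
    whose transform is numerically zero at a frequency impose no
    constraint there.  Conjugate symmetry is preserved so the output is
    real.
    """
    S_w = np.asarray(S_w, dtype=float)
    filters = np.asarray(filters, dtype=float)
    if filters.ndim == 2:
        filters = filters[None]
    C, D, L = filters.shape
    T = S_w.shape[0]
    if T < L:
        raise ValueError("movie shorter than the filter support")
    F = np.fft.rfft(S_w, axis=0)                       # nf x D
    # transform of each filter's time course per pixel, zero-padded to T
    Ahat = np.fft.rfft(filters, n=T, axis=2)           # C x D x nf
    out = F.copy()
    scale = max(np.abs(Ahat).max(), 1.0)
    for f in range(F.shape[0]):
        Af = Ahat[:, :, f].T                           # D x C
        keep = np.linalg.norm(Af, axis=0) > atol * scale
        if not keep.any():
            continue
        Cm = np.conj(Af[:, keep])
        G = Cm.conj().T @ Cm
        out[f] = F[f] - Cm @ np.linalg.lstsq(G, Cm.conj().T @ F[f], rcond=None)[0]
    return np.fft.irfft(out, n=T, axis=0)


def enforce_constraints(S: np.ndarray, A: np.ndarray, lo: float = -0.5,
                        hi: float = 0.5, var_target=None,
                        max_iter: int = 500, tol: float = 1e-9):
    """Dykstra-corrected cyclic projections onto the display constraints.

    Cycles projections onto three sets until convergence or
    ``max_iter``: the RF null space (linear projector), the pixel box
    [lo, hi] (clip), and the per-pixel temporal variance sphere
    (rescaling of the mean-removed time series to the target norm;
    ``var_target`` is a scalar or length-D array, default the input's
    per-pixel variance).  The variance set is non-convex, so Dykstra's
    convergence guarantee does not formally apply; progress is
    monitored and the final per-constraint residuals are reported.  A
    final exact null-space projection and clip are applied so the
    reported orthogonality residual is at numerical precision whenever
    the box is inactive.

    Returns
    -------
    S_out : T x D array
    report : dict with ``orthogonality`` (max |A^T S| over frames),
        ``box`` (max violation), ``variance`` (max relative variance
        error), ``iterations``, ``converged``
    """
    S = np.asarray(S, dtype=float).copy()
    T, D = S.shape
    A2 = np.atleast_2d(np.asarray(A, dtype=float))
    if A2.shape[0] != D:
        A2 = A2.T
    P = _projector(A2)
    if var_target is None:
        var_target = S.var(axis=0)
    var_target = np.broadcast_to(np.asarray(var_target, dtype=float), (D,))
    target_norm = np.sqrt(var_target * T)

    def proj_null(x):
        return x @ P.T

    def proj_box(x):
        return np.clip(x, lo, hi)

    def proj_var(x):
        mu = x.mean(axis=0)
        d = x - mu
        nrm = np.linalg.norm(d, axis=0)
        safe = np.where(nrm > 0, nrm, 1.0)
        return mu + d * np.where(nrm > 0, target_norm / safe, 0.0)

    projections = (proj_null, proj_var, proj_box)
    increments = [np.zeros_like(S) for _ in projections]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i, proj in enumerate(projections):
            y = S + increments[i]
            S_new = proj(y)
            increments[i] = y - S_new
            S = S_new
        orth = np.abs(S @ A2).max()
        box = max(0.0, float((S - hi).max()), float((lo - S).max()))
        var_err = np.abs(S.var(axis=0) - var_target).max() / max(var_target.max(), 1e-300)
        if orth < tol and box < tol and var_err < 100 * tol:
            converged = True
            break
    S = proj_box(proj_null(S))
    report = {
        "orthogonality": float(np.abs(S @ A2).max()),
        "box": max(0.0, float((S - hi).max()), float((lo - S).max())),
        "variance": float(np.abs(S.var(axis=0) - var_target).max()
                          / max(var_target.max(), 1e-300)),
        "iterations": it,
        "converged": converged,
    }
    return S, report


def quantize_8bit(S: np.ndarray, lo: float = -0.5, hi: float = 0.5) -> np.ndarray:
    """Affine map of [lo, hi] onto 0..255 with round-half-even.

    Quantization error is at most (hi - lo)/510 per entry; the
    orthogonality residual after quantization should be measured, not
    assumed.
    """
    S = np.asarray(S, dtype=float)
    if S.min() < lo - 1e-12 or S.max() > hi + 1e-12:
        raise ValueError("input outside the display range")
    q = np.rint((S - lo) / (hi - lo) * 255.0)
    return q.astype(np.uint8)
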