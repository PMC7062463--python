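"""Partitioning, model selection, PSTH accuracy, subunit geometry."""

import numpy as np
import pytest

import stclust as sc
from stclust.evaluate import (gaussian2d_fit, make_partition,
                              permutation_control, post_event_mask, psth,
                              psth_correlation, response_structure,
                              response_structure_ratio, rf_stimulus_angle,
                              select_model, tiling_statistic)
from stclust.model import SubunitBank, SubunitModel


def test_make_partition():
    p = make_partition(100, seed=0)
    assert len(p.test) == 10
    assert np.array_equal(p.test, np.arange(90, 100))  # contiguous tail
    allidx = np.sort(np.concatenate([p.train, p.validation, p.test]))
    assert np.array_equal(allidx, np.arange(100))
    q = make_partition(100, seed=0)
    assert np.array_equal(p.train, q.train)
    with pytest.raises(ValueError):
        make_partition(100, test_frac=0.6, val_frac=0.5)


def test_select_model_prefers_true_complexity():
    # LN cell (one true subunit): N* = 1 in the majority of runs
    hits = 0
    for s in range(3):
        cell = sc.toy_cell(1, dims=(3, 3), seed=40 + s, mean_rate=0.2)
        X = sc.gaussian_stimulus(40000, (3, 3), seed=140 + s)
        Y = cell.responses(X, seed=240 + s)
        n, lam, _ = select_model(X, Y, n_grid=[1, 2, 3], repeats=3,
                                 seed=340 + s)
        hits += n == 1
    assert hits >= 2


def test_select_model_lambda_zero_with_abundant_data(toy3):
    _, X, Y = toy3
    n, lam, table = select_model(X, Y, n_grid=[3], lam_grid=[0.0, 0.1, 0.3],
                                 reg="l1", repeats=2, seed=1)
    assert lam == 0.0
    # sanity: the chosen cell is not dominated anywhere on the grid
    assert table[(n, lam)] == max(table.values())


def test_psth_properties():
    rng = np.random.default_rng(2)
    rasters = rng.poisson(0.5, size=(8, 600))
    sm = psth(rasters)
    # kernel mass conservation in the interior
    assert sm[50:-50].sum() == pytest.approx(
        rasters.mean(axis=0)[50:-50].sum(), rel=2e-3)
    # sigma -> 0 returns the raw trial mean
    assert np.allclose(psth(rasters, sigma=0.0), rasters.mean(axis=0))
    # identical trials: smoothed single trial
    one = rasters[:1]
    rep = np.tile(one, (5, 1))
    assert np.allclose(psth(rep), psth(one))


def test_response_structure_sinusoid():
    T = 6000
    t = np.arange(T) / 120.0
    amp, f = 0.3, 2.0
    rate = 0.5 + amp * np.sin(2 * np.pi * f * t)
    rasters = np.tile(rate, (200, 1))
    got = response_structure(rasters, sigma=1 / 60.0)
    # smoothing attenuates a sinusoid by exp(-(2 pi f sigma)^2 / 2)
    atten = np.exp(-0.5 * (2 * np.pi * f / 60.0) ** 2)
    assert got == pytest.approx(amp**2 / 2 * atten**2, rel=0.02)
    assert response_structure(np.ones((3, 100))) == 0.0


def test_response_structure_ratio_and_event_mask():
    rng = np.random.default_rng(12)
    t = np.arange(1200) / 120.0
    modulated = np.tile(0.5 + 0.3 * np.sin(2 * np.pi * t), (50, 1))
    flat = np.full((50, 1200), 0.5) + 0.0 * modulated
    assert response_structure_ratio(flat, modulated) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        response_structure_ratio(modulated, flat)
    mask = post_event_mask([0.0, 1.0], n_bins=240, bin_width=1 / 120,
                           window=0.25)
    assert mask[:30].all() and not mask[30:120].any()
    assert mask[120:150].all() and not mask[150:].any()


def test_psth_correlation_self_consistency():
    cell = sc.toy_cell(3, dims=(4, 4), seed=3, mean_rate=0.3)
    X = sc.gaussian_stimulus(3000, (4, 4), seed=4)
    rates = cell.rates(X)
    rasters = np.stack([sc.sample_spikes(rates, seed=s).counts
                        for s in range(150)])
    model = SubunitModel(bank=SubunitBank(cell.bank.K,
                                          cell.bank.w * cell.gain))
    r = psth_correlation(model, X, rasters, seed=5)
    assert r >= 0.9
    with pytest.raises(ValueError):
        psth_correlation(model, X, np.zeros((3, 3000)), seed=6)


def test_gaussian2d_fit():
    yy, xx = np.mgrid[0:11, 0:11]
    cov = np.array([[1.8, 0.5], [0.5, 0.9]])
    prec = np.linalg.inv(cov)
    d = np.stack([xx - 6.2, yy - 4.4], axis=-1)
    img = np.exp(-0.5 * np.einsum("...i,ij,...j->...", d, prec, d))
    fit = gaussian2d_fit(img)
    assert fit.ok and fit.mse < 1e-8
    assert fit.center == pytest.approx((6.2, 4.4), abs=1e-3)
    assert np.allclose(fit.covariance, cov, atol=1e-3)
    # pixel-shuffled image fits strictly worse
    rng = np.random.default_rng(7)
    shuffled = rng.permutation(img.ravel()).reshape(img.shape)
    assert gaussian2d_fit(shuffled).mse > fit.mse
    # flat image is flagged
    assert not gaussian2d_fit(np.zeros((5, 5))).ok


def test_permutation_control():
    rng = np.random.default_rng(8)
    yy, xx = np.mgrid[0:9, 0:9]
    subs = np.stack([
        np.exp(-((yy - 2) ** 2 + (xx - 2) ** 2) / 2).ravel(),
        np.exp(-((yy - 6) ** 2 + (xx - 6) ** 2) / 2).ravel(),
    ]) + 0.01 * rng.standard_normal((2, 81))
    null_mse, q, degenerate = permutation_control(subs, 20, seed=9,
                                                  grid_shape=(9, 9))
    assert not degenerate
    assert np.all(q <= 0.1)  # compact subunits sit at the low quantiles
    assert null_mse.shape == (40,)
    # identical subunits: permutation is vacuous
    same = np.tile(subs[:1], (2, 1))
    _, q2, deg2 = permutation_control(same, 5, seed=10, grid_shape=(9, 9))
    assert deg2 and np.all(np.isnan(q2))
    with pytest.raises(ValueError):
        permutation_control(subs, 0)


def test_tiling_statistic():
    from stclust.evaluate import Gaussian2DFit
    a = Gaussian2DFit((0.0, 0.0), np.eye(2), 1.0, 0.0)
    b = Gaussian2DFit((3.0, 0.0), np.eye(2), 1.0, 0.0)
    assert np.allclose(tiling_statistic([a, b]), 3.0)
    # anisotropic case matches the direct quadratic form
    cov = np.array([[4.0, 1.0], [1.0, 2.0]])
    c = Gaussian2DFit((0.0, 0.0), cov, 1.0, 0.0)
    d = Gaussian2DFit((0.0, 5.0), np.eye(2), 1.0, 0.0)
    u = np.array([0.0, 1.0])
    expected = 5.0 / np.sqrt(np.sqrt(u @ cov @ u) * 1.0)
    assert tiling_statistic([c, d])[0] == pytest.approx(expected)
    with pytest.raises(ValueError):
        tiling_statistic([a])


def test_rf_stimulus_angle():
    rf = np.array([1.0, 0.0, 0.0])
    frames = np.array([[2.0, 0, 0], [0, 1.0, 0], [0.0, 0, 0]])
    ang = rf_stimulus_angle(frames, rf)
    assert ang[0] == pytest.approx(0.0)
    assert ang[1] == pytest.approx(90.0)
    assert np.isnan(ang[2])
    # high-dimensional Gaussian frames concentrate near 90 degrees
    rng = np.random.default_rng(11)
    D = 400
    ang = rf_stimulus_angle(rng.standard_normal((500, D)),
                            rng.standard_normal(D))
    assert abs(ang.mean() - 90.0) < 1.0
    assert ang.std() < 5.0
    with pytest.raises(ValueError):
        rf_stimulus_angle(frames, np.zeros(3))
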