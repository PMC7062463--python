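"""The spike-triggered clustering estimator and the second-stage fit."""

import numpy as np
import pytest

import stclust as sc
from stclust.clustering import (fit_output_nonlinearity, fit_subunits,
                                sta_decomposition_residual, update_activations,
                                update_filters, update_weights)
from stclust.model import SubunitBank, nll, poisson_nll


def test_update_activations_cases():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((10, 4))
    one = update_activations(X, SubunitBank(rng.standard_normal((1, 4)), [2.0]))
    assert np.allclose(one.alpha, 1.0)
    K = np.tile(rng.standard_normal(4), (3, 1))
    sym = update_activations(X, SubunitBank(K, [0.5, 0.5, 0.5]))
    assert np.allclose(sym.alpha, 1.0 / 3.0)
    with pytest.raises(ValueError):
        update_activations(X, SubunitBank(K, [0.0, 0.0, 0.0]))


def test_update_activations_matches_naive_softmax():
    rng = np.random.default_rng(1)
    K = rng.standard_normal((3, 5))
    w = rng.uniform(0.1, 1, 3)
    X = rng.standard_normal((7, 5))
    naive = w * np.exp(X @ K.T)
    naive /= naive.sum(axis=1, keepdims=True)
    got = update_activations(X, SubunitBank(K, w)).alpha
    assert np.allclose(got, naive, atol=1e-12)
    assert np.allclose(got.sum(axis=1), 1.0, atol=1e-9)


def test_update_filters_cases_and_oracle():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((20, 4))
    Y = rng.poisson(1.0, 20) + 1
    # all responsibility on subunit 0: its filter is the STA
    alpha = np.zeros((20, 2))
    alpha[:, 0] = 1.0
    K = update_filters(X, Y, alpha, rng=rng)
    assert np.allclose(K[0], (Y @ X) / Y.sum())
    # uniform responsibilities: both filters equal the STA
    alpha = np.full((20, 2), 0.5)
    K = update_filters(X, Y, alpha)
    assert np.allclose(K[0], K[1])
    assert np.allclose(K[0], (Y @ X) / Y.sum())
    # random responsibilities match the double loop
    alpha = rng.dirichlet(np.ones(3), size=20)
    K = update_filters(X, Y, alpha)
    for n in range(3):
        num = sum(Y[t] * alpha[t, n] * X[t] for t in range(20))
        den = sum(Y[t] * alpha[t, n] for t in range(20))
        assert np.allclose(K[n], num / den, atol=1e-12)


def test_update_filters_empty_cluster():
    X = np.random.default_rng(3).standard_normal((5, 2))
    Y = np.ones(5)
    alpha = np.zeros((5, 2))
    alpha[:, 0] = 1.0
    with pytest.raises(ValueError):
        update_filters(X, Y, alpha)
    log = []
    rng = np.random.default_rng(4)
    K = update_filters(X, Y, alpha, rng=rng, rescue_log=log, iteration=3)
    assert log == [(3, 1)]
    assert any(np.allclose(K[1], X[t]) for t in range(5))


def test_update_weights():
    rng = np.random.default_rng(5)
    Y = rng.poisson(1.0, 30) + 1
    alpha = np.ones((30, 1))
    # single zero filter: weight equals the mean spike count per bin
    w = update_weights(Y, alpha, np.zeros((1, 4)), n_bins=100)
    assert w[0] == pytest.approx(Y.sum() / 100)
    # doubling counts doubles weights
    w2 = update_weights(2 * Y, alpha, np.zeros((1, 4)), n_bins=100)
    assert w2[0] == pytest.approx(2 * w[0])


def test_fixed_point_strengths_sum_to_mean_rate(toy3, toy3_fit):
    # Eq. 6 stationarity: sum of strengths equals the mean spike rate
    _, X, Y = toy3
    bank, _ = toy3_fit
    assert bank.strengths.sum() == pytest.approx(Y.counts.mean(), rel=1e-3)


def test_single_subunit_fit_equals_sta(toy3):
    _, X, Y = toy3
    bank, trace = sc.fit_subunits(X, Y, 1, seed=0)
    sta = (Y.counts @ X.frames) / Y.counts.sum()
    cos = bank.K[0] @ sta / (np.linalg.norm(bank.K[0]) * np.linalg.norm(sta))
    assert cos > 0.999
    idx = Y.counts > 0
    resid = sta_decomposition_residual(bank, X.frames[idx], Y.counts[idx])
    assert abs(resid) < 1e-6


def test_fit_recovers_toy_subunits(toy3, toy3_fit):
    cell, X, Y = toy3
    bank, trace = toy3_fit
    pairs, _ = sc.match_subunits(cell.bank, bank)
    assert min(c for *_, c in pairs) > 0.95
    assert trace.monotone
    # bank is sorted by strength
    s = bank.strengths
    assert np.all(np.diff(s) <= 1e-12)


def test_surrogate_monotone_across_seeds(toy3):
    _, X, Y = toy3
    sub = slice(0, 20000)
    for seed in range(3):
        _, trace = sc.fit_subunits(X.frames[sub], Y.counts[sub], 4, seed=seed,
                                   max_iter=40)
        assert trace.monotone


def test_sta_decomposition_residual_after_convergence(toy3, toy3_fit):
    _, X, Y = toy3
    bank, _ = toy3_fit
    idx = Y.counts > 0
    resid = sta_decomposition_residual(bank, X.frames[idx], Y.counts[idx])
    assert resid < 1e-3


def test_fit_requires_spikes_and_valid_n(toy3):
    _, X, _ = toy3
    with pytest.raises(ValueError):
        sc.fit_subunits(X, np.zeros(X.n_frames, dtype=int), 2)
    with pytest.raises(ValueError):
        sc.fit_subunits(X, np.ones(X.n_frames, dtype=int), 0)


def test_output_nonlinearity_recovery_identity(toy3):
    # data generated with the identity g: stage 2 should find a ~ 1, b ~ 0
    cell, X, Y = toy3
    bank, _ = sc.fit_subunits(X, Y, 3, seed=1)
    model = fit_output_nonlinearity(X, Y, bank, seed=2)
    assert 0.9 <= model.nonlinearity.a <= 1.1
    assert model.nonlinearity.b < 0.05


def test_output_nonlinearity_detects_saturation():
    # data generated with b=1: freeing b must beat forcing b ~ 0 held out
    from stclust.model import OutputNonlinearity
    cell = sc.toy_cell(2, dims=(3, 3), seed=3, mean_rate=0.3,
                       nonlinearity=OutputNonlinearity(1.0, 1.0))
    X = sc.gaussian_stimulus(100000, (3, 3), seed=4)
    Y = cell.responses(X, seed=5)
    Xtr, Ytr = X.frames[:80000], Y.counts[:80000]
    Xte, Yte = X.frames[80000:], Y.counts[80000:]
    bank, _ = sc.fit_subunits(Xtr, Ytr, 2, seed=6)
    free = fit_output_nonlinearity(Xtr, Ytr, bank, seed=7)
    assert free.nonlinearity.b > 0.1
    from stclust.model import firing_rate
    # linear comparison model: the clustering-stage bank as-is (b = 0,
    # weights calibrated by the weight update)
    nll_free = poisson_nll(firing_rate(free, Xte), Yte)
    nll_forced = poisson_nll(sc.generator_signal(bank, Xte), Yte)
    assert nll_free < nll_forced


def test_output_nonlinearity_does_not_degrade_self_fit(toy3):
    cell, X, Y = toy3
    bank, _ = sc.fit_subunits(X, Y, 3, seed=8)
    before = poisson_nll(sc.generator_signal(bank, X), Y.counts)
    model = fit_output_nonlinearity(X, Y, bank, seed=9)
    after = nll(model, X, Y)
    assert after <= before + 1e-9
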