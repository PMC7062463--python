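"""Hierarchical splitting: initialization, factorized assignments, paths."""

import itertools

import numpy as np
import pytest

import stclust as sc
from stclust.hierarchy import child_assignments, fit_path, match_subunits, split_init
from stclust.model import SubunitBank, expected_nll
from stclust.clustering import update_activations, _spike_frames


def test_split_init():
    rng = np.random.default_rng(0)
    bank = SubunitBank(rng.standard_normal((3, 8)), np.array([0.5, 0.3, 0.2]))
    out = split_init(bank, 1, noise_sd=0.0, seed=1)
    assert out.n_subunits == 4
    # noiseless children are identical copies of the parent
    assert np.allclose(out.K[-1], bank.K[1])
    assert np.allclose(out.K[-2], bank.K[1])
    # weights divided exactly in two; strengths sum to the parent strength
    assert out.w[-1] == bank.w[1] / 2 and out.w[-2] == bank.w[1] / 2
    assert out.strengths[-2:].sum() == pytest.approx(bank.strengths[1])
    # other subunits bit-identical
    assert np.array_equal(out.K[:2], bank.K[[0, 2]])
    with pytest.raises(IndexError):
        split_init(bank, 5)


def test_child_assignments_conservation_and_symmetry():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((50, 6))
    alpha_parent = rng.uniform(0, 1, 50)
    K = rng.standard_normal((2, 6))
    # identical children split the parent mass in half
    same = child_assignments(X, alpha_parent, np.tile(K[0], (2, 1)),
                             np.array([0.2, 0.2]))
    assert np.allclose(same[:, 0], alpha_parent / 2)
    # conservation to the last bit for arbitrary children
    ac = child_assignments(X, alpha_parent, K, np.array([0.3, 0.1]))
    assert np.abs(ac.sum(axis=1) - alpha_parent).max() <= 2 * np.finfo(float).eps


def test_child_assignments_match_flat_softmax_when_sum_condition_holds():
    # construct children whose activations sum to the parent's:
    # e^{K.X+b} = e^{K1.X+b1} + e^{K2.X+b2} holds when K1 = K2 = K and
    # the child weights sum to the parent weight
    rng = np.random.default_rng(2)
    X = rng.standard_normal((40, 5))
    K_others = rng.standard_normal((1, 5))
    K_parent = rng.standard_normal(5)
    w_others, w_parent = np.array([0.4]), 0.6
    flat_parent = update_activations(
        X, SubunitBank(np.vstack([K_others, K_parent]),
                       np.array([0.4, w_parent]))).alpha
    w_children = np.array([0.25, 0.35])
    flat_children = update_activations(
        X, SubunitBank(np.vstack([K_others, K_parent, K_parent]),
                       np.concatenate([w_others, w_children]))).alpha
    ac = child_assignments(X, flat_parent[:, 1],
                           np.vstack([K_parent, K_parent]), w_children)
    assert np.allclose(ac, flat_children[:, 1:], atol=1e-12)


def test_fit_path_trivial_and_monotone(toy3):
    _, X, Y = toy3
    sub = slice(0, 30000)
    Xs, ys, n_bins = _spike_frames(X.frames[sub], Y.counts[sub])
    path1 = fit_path(X.frames[sub], Y.counts[sub], 1, seed=3)
    assert path1.n_levels == 1 and path1.gains == []
    path = fit_path(X.frames[sub], Y.counts[sub], 4, seed=3)
    assert [b.n_subunits for b in path.levels] == [1, 2, 3, 4]
    # training approximate likelihood never decreases along the path
    nlls = [expected_nll(b, Xs, ys, n_bins) for b in path.levels]
    assert np.all(np.diff(nlls) <= 1e-9)
    assert np.allclose(path.gains, -np.diff(nlls), atol=1e-12)


def test_fit_path_recovers_toy_with_diminishing_gains(toy3):
    cell, X, Y = toy3
    path = fit_path(X, Y, 4, seed=4)
    pairs, _ = match_subunits(cell.bank, path.bank_at(3))
    assert min(c for *_, c in pairs) >= 0.95
    # splitting beyond the true subunit count buys much less
    assert path.gains[2] < path.gains[1]


def test_match_subunits_identity_and_permutation():
    rng = np.random.default_rng(5)
    K = rng.standard_normal((4, 10))
    bank = SubunitBank(K, np.full(4, 0.25))
    pairs, un = match_subunits(bank, bank)
    assert un == [] and all(i == j for i, j, _ in pairs)
    assert all(c == pytest.approx(1.0) for *_, c in pairs)
    perm = [2, 0, 3, 1]
    pairs, _ = match_subunits(bank, SubunitBank(K[perm], np.full(4, 0.25)))
    assert sorted((i, j) for i, j, _ in pairs) == [(0, 1), (1, 3), (2, 0), (3, 2)]


def test_match_subunits_greedy_vs_exhaustive_adversarial():
    # classic case where greedy matching is suboptimal in total similarity
    a = np.array([[1.0, 0.0], [np.cos(0.5), np.sin(0.5)]])
    b = np.array([[np.cos(0.25), np.sin(0.25)], [1.0, 0.0]])
    A = SubunitBank(a, [0.5, 0.5])
    B = SubunitBank(b, [0.5, 0.5])
    pairs, _ = match_subunits(A, B)
    sim = (a / np.linalg.norm(a, axis=1, keepdims=True)) @ \
          (b / np.linalg.norm(b, axis=1, keepdims=True)).T
    # greedy grabs the single largest inner product first
    first = max(((i, j) for i in range(2) for j in range(2)),
                key=lambda ij: sim[ij])
    assert (first[0], first[1]) in {(i, j) for i, j, _ in pairs}
    # exhaustive assignment can differ; document the greedy answer
    best_total = max(sum(sim[i, p[i]] for i in range(2))
                     for p in itertools.permutations(range(2)))
    greedy_total = sum(sim[i, j] for i, j, _ in pairs)
    assert greedy_total <= best_total + 1e-12
    with pytest.raises(ValueError):
        match_subunits(A, SubunitBank(np.zeros((4, 2)), np.full(4, 0.1)))


def test_hierarchical_matches_flat_heldout(toy3):
    _, X, Y = toy3
    from stclust.evaluate import make_partition, validation_ll
    part = make_partition(X.n_frames, seed=6)
    Xtr, Ytr = X.frames[part.train], Y.counts[part.train]
    path = fit_path(Xtr, Ytr, 2, seed=7)
    flat, _ = sc.fit_subunits(Xtr, Ytr, 2, seed=7)
    h = validation_ll(path.bank_at(2), X, Y, part.test)
    f = validation_ll(flat, X, Y, part.test)
    assert h >= f - 0.01 * abs(f)
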