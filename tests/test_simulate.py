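"""Ground-truth generators: mosaic geometry, cascade calibration, toys."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import stclust as sc
from stclust.simulate import assign_bipolars, make_mosaic, rgc_cell, toy_cell


def nn_distances(pos):
    d = squareform(pdist(pos))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def test_mosaic_exact_lattice_without_jitter():
    m = make_mosaic(jitter_sd=0.0, seed=0)
    assert m.n_cones == 64
    nn = nn_distances(m.positions)
    assert np.abs(nn - 5.0).max() < 1e-9


def test_mosaic_determinism_and_jitter_statistics():
    a = make_mosaic(seed=1)
    b = make_mosaic(seed=1)
    assert np.array_equal(a.positions, b.positions)
    means = [nn_distances(make_mosaic(seed=s).positions).mean()
             for s in range(100)]
    # jitter sd 0.35 per axis: the min over ~6 neighbors sits ~1.5 relative
    # displacement sds below the 5 g.u. lattice spacing
    assert 4.3 <= np.mean(means) <= 5.2
    assert np.std(means) < 0.1


def test_mosaic_orientation():
    # lattice rows run at 60 degrees to the stimulus grid axes
    m0 = make_mosaic(jitter_sd=0.0, angle_deg=0.0, seed=0)
    m60 = make_mosaic(jitter_sd=0.0, angle_deg=60.0, seed=0)
    th = np.deg2rad(60.0)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    assert np.allclose(m60.positions, m0.positions @ R.T, atol=1e-9)


def test_assign_bipolars():
    m = make_mosaic(seed=2)
    labels = assign_bipolars(m, k=64, seed=0)
    assert len(np.unique(labels)) == 64  # singleton clusters
    labels1 = assign_bipolars(m, k=1, seed=0)
    assert np.all(labels1 == 0)
    sizes = []
    for s in range(20):
        lab = assign_bipolars(make_mosaic(seed=s), k=12, seed=s)
        sizes.extend(np.bincount(lab, minlength=12))
    # 64 cones over 12 bipolar cells: cluster sizes stay near 64/12
    assert min(sizes) >= 2 and max(sizes) <= 9
    assert abs(np.mean(sizes) - 64 / 12) < 1e-9
    with pytest.raises(ValueError):
        assign_bipolars(m, k=65)


def test_rgc_cell_calibration_and_linearity():
    cell = rgc_cell(seed=3)
    # fresh 2-minute draw: mean rate near the 19 spikes/s target
    raw = sc.white_noise(2 * 60 * 120, cell.grid_shape, contrast=0.48, seed=4)
    rates, spk = sc.simulate_cell(cell, raw, seed=5)
    hz = rates.mean() / cell.bin_width
    assert abs(hz - 19.0) / 19.0 < 0.1
    # zero-contrast stimulus: constant rate sum(w_b) * gain
    flat = cell.rates(np.zeros((10, cell.pooling.shape[1])))
    assert np.allclose(flat, flat[0])
    assert flat[0] == pytest.approx(
        cell.output_gain * cell.bipolar_weights.sum())
    # doubling the bipolar weights doubles the (pre-Poisson) rate
    cell.bipolar_weights = 2 * cell.bipolar_weights
    assert np.allclose(cell.rates(raw[:100]), 2 * rates[:100])


def test_true_subunits_tile_the_mosaic():
    cell = rgc_cell(seed=6)
    maps = cell.true_subunits
    assert maps.shape[0] == 12
    # every cone's pooling mass lands in exactly one subunit
    assert np.allclose(maps.sum(axis=0), cell.pooling.sum(axis=0), atol=1e-12)
    # subunits are spatially compact: mass concentrated near the centroid
    rows, cols = cell.grid_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    for m in maps:
        img = m.reshape(rows, cols)
        tot = img.sum()
        cy = (yy * img).sum() / tot
        cx = (xx * img).sum() / tot
        rms = np.sqrt((((yy - cy) ** 2 + (xx - cx) ** 2) * img).sum() / tot)
        assert rms < 2.5  # pixels


def test_white_noise_values_and_determinism():
    w = sc.white_noise(5000, (4, 4), contrast=0.48, seed=7)
    assert set(np.unique(w)) == {-0.24, 0.24}
    assert abs(w.mean()) < 0.01
    assert np.allclose(w.var(axis=0), 0.24**2, atol=0.001)
    assert np.array_equal(w, sc.white_noise(5000, (4, 4), contrast=0.48, seed=7))
    g = sc.white_noise(20000, 16, contrast=0.48, binary=False, seed=8)
    assert np.allclose(g.std(axis=0), 0.24, atol=0.01)
    with pytest.raises(ValueError):
        sc.white_noise(10, 4, contrast=0.0)


def test_image_jitter_stimulus_hook():
    from stclust.simulate import image_jitter_stimulus
    rng = np.random.default_rng(30)
    img = rng.uniform(0, 1, (20, 20))
    offsets = np.array([[0, 0], [2, 3], [5, 5]])
    frames = image_jitter_stimulus(img, offsets, (4, 4), origin=(5, 5))
    assert frames.shape == (3, 16)
    expected = img[7:11, 8:12].ravel() - img.mean()
    assert np.allclose(frames[1], expected)
    with pytest.raises(ValueError):
        image_jitter_stimulus(img, np.array([[30, 0]]), (4, 4))


def test_toy_cell_construction():
    # 2-D version: unit-norm filters at distinct angles
    cell = toy_cell(3, dims=2, seed=9)
    assert cell.filters.shape == (3, 2)
    assert np.allclose(np.linalg.norm(cell.filters, axis=1), 1.0)
    angles = np.arctan2(cell.filters[:, 1], cell.filters[:, 0])
    assert len(np.unique(np.round(angles, 6))) == 3
    # grid version: localized unit-norm bumps at distinct centers
    cell = toy_cell(5, dims=(5, 5), seed=10)
    assert cell.filters.shape == (5, 25)
    assert np.allclose(np.linalg.norm(cell.filters, axis=1), 1.0)
    overlaps = cell.filters @ cell.filters.T - np.eye(5)
    assert overlaps.max() < 0.8  # distinct centers
    # calibrated mean rate under a standard-Gaussian stimulus
    X = sc.gaussian_stimulus(50000, (5, 5), seed=11)
    assert cell.rates(X).mean() == pytest.approx(0.12, rel=0.05)
    # determinism of responses
    a = cell.responses(X, seed=12).counts
    b = cell.responses(X, seed=12).counts
    assert np.array_equal(a, b)


def test_toy_cell_refit_recovers_filters():
    cell = toy_cell(3, dims=(4, 4), seed=13)
    X = sc.gaussian_stimulus(120000, (4, 4), seed=14)
    Y = cell.responses(X, seed=15)
    bank, _ = sc.fit_subunits(X, Y, 3, seed=16, max_iter=200)
    pairs, _ = sc.match_subunits(cell.bank, bank)
    assert min(c for *_, c in pairs) >= 0.95


def test_five_subunit_refits_are_stable_across_seeds():
    """Consistency fixture: refits of the same 5-subunit cell from
    different initializations agree pairwise."""
    cell = toy_cell(5, dims=(5, 5), seed=17, mean_rate=0.2)
    X = sc.gaussian_stimulus(150000, (5, 5), seed=18)
    Y = cell.responses(X, seed=19)
    banks = [sc.fit_subunits(X, Y, 5, seed=s, max_iter=150)[0]
             for s in range(3)]
    for a in range(len(banks)):
        for b in range(a + 1, len(banks)):
            pairs, _ = sc.match_subunits(banks[a], banks[b])
            assert min(c for *_, c in pairs) >= 0.9
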