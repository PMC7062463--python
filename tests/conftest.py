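import numpy as np
import pytest

import stclust as sc


@pytest.fixture(scope="session")
def toy3():
    """3-subunit toy cell on a 4x4 grid with a 60k-frame recording."""
    cell = sc.toy_cell(3, dims=(4, 4), seed=11)
    X = sc.gaussian_stimulus(60000, (4, 4), seed=12)
    Y = cell.responses(X, seed=13)
    return cell, X, Y


@pytest.fixture(scope="session")
def toy3_fit(toy3):
    """Converged unregularized N=3 fit to the toy recording."""
    _, X, Y = toy3
    bank, trace = sc.fit_subunits(X, Y, 3, seed=14, max_iter=200)
    return bank, trace


@pytest.fixture(scope="session")
def rgc_recording():
    """Default simulated RGC with a 24-minute white-noise recording."""
    cell = sc.rgc_cell(seed=21)
    T = 24 * 60 * 120
    raw = sc.white_noise(T, cell.grid_shape, seed=22).astype(np.float32)
    rates, spk = sc.simulate_cell(cell, raw, seed=23)
    return cell, raw, rates, spk
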