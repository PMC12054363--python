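"""Shared fixtures: toy cells, models and simulated data sets.

Expensive simulated sets (Wilson intensities, disorder data) are
session-scoped so the statistics tests share them.
"""

import numpy as np
import pytest

import xtaldecon as xd

from helpers import random_two_chain_model


@pytest.fixture
def cube_cell():
    return xd.UnitCell(10.0, 10.0, 10.0)


@pytest.fixture
def ortho_cell():
    return xd.UnitCell(15.0, 21.0, 27.0)


@pytest.fixture
def two_chain_factory():
    return random_two_chain_model


@pytest.fixture(scope="session")
def wilson_set():
    """Ideal untwinned acentric data on an a = b cell (twin-op friendly)."""
    return xd.wilson_intensities(xd.UnitCell(30.0, 30.0, 40.0), "P1", 1.55, seed=4)


@pytest.fixture(scope="session")
def twofold_op():
    """Proper twofold index permutation (h,k,l) -> (k,h,-l)."""
    return np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]])


@pytest.fixture(scope="session")
def noise_free_disorder():
    """Period-3 sparse-layer spec without noise, plus its simulated data."""
    spec = xd.DisorderSpec(amplitude_noise_fraction=0.0, seed=1)
    return spec, xd.simulate_bragg(spec, d_min=2.0)
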