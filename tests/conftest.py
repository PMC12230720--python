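"""Shared fixtures: small synthetic chains, complexes and maps.

Expensive objects are session-scoped; tests must not mutate them (operations
under test return copies).
"""

import numpy as np
import pytest

from emfit.map_core import DensityMap, normalize, resample
from emfit.simulate import (
    SyntheticComplexSpec,
    ground_truth_labels,
    make_duplex_chain,
    make_helix_chain,
    make_toy_complex,
    simulate_map,
)


@pytest.fixture(scope="session")
def helix60():
    return make_helix_chain("A", 60)


@pytest.fixture(scope="session")
def kinked120():
    """The standard single-chain fitting fixture: two-armed kinked helix."""
    return make_helix_chain("A", 120, kink_at=45, kink_angle_deg=55.0)


@pytest.fixture(scope="session")
def duplex16():
    return make_duplex_chain("D", 16, np.random.default_rng(5))


@pytest.fixture(scope="session")
def toy_complex():
    """Two kinked protein chains + one rigid 30-bp duplex (default recipe)."""
    return make_toy_complex(SyntheticComplexSpec(seed=11))


@pytest.fixture(scope="session")
def toy_map(toy_complex):
    """Noise-free 5 Å map of the toy complex on the 1 Å lattice."""
    return simulate_map(toy_complex, resolution=5.0, voxel_size=1.0)


@pytest.fixture(scope="session")
def toy_labels(toy_complex, toy_map):
    return ground_truth_labels(toy_complex, toy_map)


@pytest.fixture(scope="session")
def kinked120_map(kinked120):
    """Normalized 2 Å working map of the kinked-helix fixture."""
    dmap = simulate_map(kinked120, resolution=5.0, voxel_size=1.0)
    return resample(normalize(dmap), 2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def ramp_map():
    """Linear density ramp f(x, y, z) = x on a 2 Å lattice."""
    nz, ny, nx = 12, 12, 12
    grid = np.broadcast_to(np.arange(nx, dtype=np.float32) * 2.0,
                           (nz, ny, nx)).copy()
    return DensityMap(grid=grid, voxel_size=2.0, origin=np.zeros(3),
                      resolution=6.0)
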