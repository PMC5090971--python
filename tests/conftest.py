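import numpy as np
import pytest

from fracperm.classical import ClassicalModel, SpatialGrid
from fracperm.profiles import Profile


@pytest.fixture(scope="session")
def default_grid():
    """The full-resolution solver grid (±45 Å, h = 0.5 Å, 181 nodes)."""
    return SpatialGrid(-45.0, 45.0, 0.5)


@pytest.fixture(scope="session")
def desk_grid():
    """Reduced inference grid (±20 Å, h = 1 Å, 41 nodes)."""
    return SpatialGrid(-20.0, 20.0, 1.0)


@pytest.fixture(scope="session")
def two_well_model(default_grid):
    """Gentle two-well landscape (2 kcal/mol barrier) with analytic force."""
    g = default_grid
    z = g.z
    w = 2.0 * ((z / 30.0) ** 2 - 1.0) ** 2
    F = -2.0 * 2 * ((z / 30.0) ** 2 - 1.0) * 2 * z / 30.0 ** 2
    model = ClassicalModel(g, np.full(g.n, 200.0), F_nodes=F)
    return model, w


@pytest.fixture(scope="session")
def flat_water_model(default_grid):
    """Force-free model at the bulk-water diffusivity 480 Å²/ns."""
    g = default_grid
    return ClassicalModel(g, np.full(g.n, 480.0))


def smooth_anchored_pmf(z, rng, max_height=2.5):
    """Random smooth bump PMF with compact support (zero at both walls)."""
    w = np.zeros_like(z)
    for _ in range(int(rng.integers(2, 5))):
        c = rng.uniform(-20, 20)
        s = rng.uniform(4, 10)
        a = rng.uniform(0.5, max_height)
        w += a * np.exp(-((z - c) / s) ** 2)
    return w * np.exp(-(z / 28.0) ** 8)
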