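import numpy as np
import pytest

from geohab.raster_io import Grid
from geohab.synthetic_landscape import Feature, LandscapeSpec, make_dem


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def constant_grid():
    return Grid(np.full((12, 12), 7.0), cellsize=30.0)


@pytest.fixture
def hill_dem():
    """Single Gaussian hill, no noise: summit value known in closed form."""
    spec = LandscapeSpec(
        nrows=31, ncols=31, cellsize=30.0, base_elevation=100.0,
        features=[Feature("hill", (15, 15), 100.0, 150.0)], noise_sd=0.0)
    return make_dem(spec)


@pytest.fixture
def south_ramp():
    """Plane dipping due south, 1 m drop per 30 m cell."""
    rows = np.arange(20)[:, None] * np.ones((1, 16))
    return Grid(200.0 - rows, cellsize=30.0)


def random_grid(rng, nrows=12, ncols=12, cellsize=30.0):
    return Grid(rng.uniform(0.0, 100.0, (nrows, ncols)), cellsize=cellsize)
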