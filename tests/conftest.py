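import numpy as np
import pytest

from fraglands.connectivity import build_cost_matrix
from fraglands.synthetic_data import make_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(20170809)


@pytest.fixture(scope="session")
def small_scenario():
    """One short transect with three zones; cheap enough for many tests."""
    return make_scenario("single-transect-small", seed=11)


@pytest.fixture(scope="session")
def small_cost_matrix(small_scenario):
    s = small_scenario
    return build_cost_matrix(
        s.resistance,
        s.sites,
        budget=s.params.female_budget,
        pixel_size=s.raster.pixel_size,
        origin_xy=s.raster.origin,
    )


@pytest.fixture(scope="session")
def toy_scenario():
    """Two green patches split by an impassable building wall."""
    return make_scenario("two-patch-toy", seed=3)
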