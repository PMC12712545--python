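import numpy as np
import pytest

from gapscape.core_io import Grid, LandUseMap
from gapscape.synthetic_landscape import LandscapeScenario, generate_scenario


@pytest.fixture(scope="session")
def default_scenario_data():
    """The default desk-scale scenario (seed 1), generated once."""
    return generate_scenario(LandscapeScenario(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_geom():
    return Grid(values=np.zeros((20, 20)), cell_size_m=1000.0)


def make_landuse(codes: np.ndarray, cell_size_m: float = 1000.0) -> LandUseMap:
    return LandUseMap(grid=Grid(values=np.asarray(codes, dtype=np.int64),
                                cell_size_m=cell_size_m))
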