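import warnings

import numpy as np
import pytest

from coastcore.grids import Raster
from coastcore.workbench import RunConfig, build_design

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def design42():
    """Full synthetic scenario at the default seed, shared across tests."""
    return build_design(RunConfig(seed=42))


@pytest.fixture(scope="session")
def run_config42():
    return RunConfig(seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_raster(data, cell_m=5.0, origin=(0.0, 0.0)):
    return Raster(np.asarray(data, dtype=float), cell_m=cell_m, origin=origin)


@pytest.fixture()
def strip_raster():
    """4 land cells in a row surrounded by sea (NaN), cell 5 m."""
    data = np.full((3, 6), np.nan)
    data[1, 1:5] = 1.0
    return make_raster(data)
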