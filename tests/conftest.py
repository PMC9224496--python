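import numpy as np
import pytest

from pulserad import default_library
from pulserad.spectra import default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def library(grid):
    return default_library(grid)


@pytest.fixture(scope="session")
def time_grid():
    return np.geomspace(2e-7, 1.7e-4, 40)
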