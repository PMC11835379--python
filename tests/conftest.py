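import numpy as np
import pytest

from dtpdyn.grid import Grid
from dtpdyn.params import CellularParams, DoseSchedule, EpigeneticParams


@pytest.fixture
def ep():
    return EpigeneticParams()


@pytest.fixture
def cp():
    return CellularParams()


@pytest.fixture
def small_grid():
    return Grid(nx=40, ny=40)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def seven_seven():
    return DoseSchedule.intermittent(tau_on=7, tau_off=7)
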