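import numpy as np
import pytest

from spadflim.core import IRFSpec, SimGrid
from spadflim.simulate import make_irf


@pytest.fixture(scope="session")
def grid():
    return SimGrid()


@pytest.fixture(scope="session")
def irf(grid):
    return make_irf(IRFSpec(), grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
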