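import numpy as np
import pytest

from angioturing.params import default_parameters
from angioturing.pde_core import FieldState, Grid2D


@pytest.fixture
def params():
    return default_parameters()


@pytest.fixture
def grid():
    """Small Neumann grid on [0,1]^2."""
    return Grid2D(Nx=21, Ny=21, La=1.0, Lb=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_state(grid):
    return FieldState.uniform(grid, n=1.0, c=0.5, d=0.2, o=1.0)
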