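import numpy as np
import pytest

from mpsir import (NodeInit, TimeGrid, exponential_recovery,
                   make_symmetric_graph, markovian_kernel)


@pytest.fixture
def coarse_grid():
    """Small grid for unit tests; acceptance runs use dt=0.005."""
    return TimeGrid(t_max=2.0, dt=0.02)


@pytest.fixture
def fine_grid():
    return TimeGrid(t_max=4.0, dt=0.005)


@pytest.fixture
def path3():
    return make_symmetric_graph("path", length=3)


@pytest.fixture
def triangle():
    return make_symmetric_graph("cycle", length=3)


@pytest.fixture
def unit_markovian():
    return markovian_kernel(1.0, 1.0)


@pytest.fixture
def unit_recovery():
    return exponential_recovery(1.0)


@pytest.fixture
def init_z09(path3):
    return NodeInit.homogeneous(3, 0.9, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
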