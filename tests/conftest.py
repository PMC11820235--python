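import numpy as np
import pytest

from noisynav import AgentParams, chain_1d, grid_2d


@pytest.fixture
def chain():
    return chain_1d()


@pytest.fixture
def grid():
    return grid_2d()


@pytest.fixture
def params():
    return AgentParams()


@pytest.fixture
def rng():
    return np.random.RandomState(1234)
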