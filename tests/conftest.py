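import numpy as np
import pytest

from extenderopt.evolution import DEConfig
from extenderopt.formulation_space import control_extender, default_space
from extenderopt.virtual_lab import NoiseModel, default_surface


@pytest.fixture(scope="session")
def space():
    return default_space()


@pytest.fixture(scope="session")
def surface():
    return default_surface()


@pytest.fixture(scope="session")
def control(space):
    return control_extender(space)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def de_cfg():
    return DEConfig(seed=7)


@pytest.fixture
def noiseless():
    return NoiseModel(sd_bull=0.0, sd_within=0.0)
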