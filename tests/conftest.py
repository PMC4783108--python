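import numpy as np
import pytest
from hypothesis import settings

from crowdspt import ModelConfig, SolutionState, product_geometry, sphere_geometry

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

SIGMA = 3.6


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def reactant():
    return sphere_geometry(SIGMA, SIGMA)


@pytest.fixture(scope="session")
def product():
    return product_geometry(0.0, SIGMA)


@pytest.fixture
def state02():
    return SolutionState(0.2)


@pytest.fixture(scope="session")
def phi_grid():
    return np.linspace(0.01, 0.4, 14)
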