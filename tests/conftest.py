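import numpy as np
import pytest
from hypothesis import settings

from vpconn.synth import SynthConfig, generate_connectome

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_connectome():
    """One default synthetic connectome (seed 1) shared across tests."""
    return generate_connectome(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def conn(default_connectome):
    return default_connectome[0]


@pytest.fixture(scope="session")
def gt(default_connectome):
    return default_connectome[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
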