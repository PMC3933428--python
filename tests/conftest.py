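import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bivalens.synthetic_data import ToySystemSpec, make_toy_system

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_system():
    """Default toy receptor/ligand system shared across tests (read-only)."""
    return make_toy_system(ToySystemSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
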