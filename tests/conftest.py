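import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def model():
    """The default intact visuomotor model (canonical repertoire)."""
    from apraxim import build_world

    return build_world()


@pytest.fixture(scope="session")
def noiseless_model():
    """Default world with exact kinematic perception (epsilon = 0)."""
    from apraxim import WorldConfig, build_world

    return build_world(WorldConfig(epsilon=0.0, epsilon_tool=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
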