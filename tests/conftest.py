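import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cascade():
    from runtumble.cascade import default_params
    return default_params()


@pytest.fixture(scope="session")
def background():
    return {"MeAsp": 0.1}


@pytest.fixture(scope="session")
def background_steady_state(default_cascade, background):
    from runtumble.cascade import steady_state
    return steady_state(default_cascade, background)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
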