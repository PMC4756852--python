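import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from laserddr import META, MIRA_900

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mira():
    return MIRA_900


@pytest.fixture(scope="session")
def meta():
    return META


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
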