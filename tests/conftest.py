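import pytest
from hypothesis import HealthCheck, settings

from tppplike import default_model, load_taxonomy, synthetic_parts

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def parts():
    return synthetic_parts()


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()
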