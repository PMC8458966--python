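import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_phantom_spec():
    """16^3 phantom spec shared by the slower training tests."""
    from longimpute.synthetic import PhantomSpec

    return PhantomSpec(shape=(16, 16, 16), seed=5)


@pytest.fixture(scope="session")
def desk_phantom_spec():
    """Default 32^3 phantom spec."""
    from longimpute.synthetic import PhantomSpec

    return PhantomSpec(seed=5)
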