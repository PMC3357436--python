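import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from vitdmr import synthdata


@pytest.fixture(scope="session")
def model_1958bc():
    return synthdata.cohort_model_1958bc()


@pytest.fixture(scope="session")
def big_cohort(model_1958bc):
    """One large cohort shared across read-only tests (n = 20,000, seed 2024)."""
    return synthdata.simulate_cohort(model_1958bc, 20_000, seed=2024)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
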