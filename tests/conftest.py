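import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_phantom():
    from ctbca import PhantomSpec, make_phantom

    return make_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """Default simulated cohort at the clinical sample size (n = 71)."""
    from ctbca import CohortSpec, simulate_cohort

    return simulate_cohort(CohortSpec(n=71, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
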