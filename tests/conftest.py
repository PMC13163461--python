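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
def cohort_50k():
    """One large default-config cohort shared by the marginal-calibration
    tests (generation is the expensive part)."""
    from cardioage import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_patients=50_000, seed=123))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240501)
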