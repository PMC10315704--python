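import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def schedule():
    from fetpwi.kinetics import FrameSchedule

    return FrameSchedule.default_dynamic()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort_frame():
    """One 80-patient synthetic cohort, shared across tests that only read it."""
    from fetpwi.simulate import generate_cohort

    return generate_cohort(80, seed=3).to_frame()
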