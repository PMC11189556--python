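import numpy as np
import pytest

from eftrial import CohortConfig, generate_cohort
from eftrial.policies import ResponderPolicy, make_policy

from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_control=20, n_intervention=20,
                                        n_classrooms=4, seed=11))


@pytest.fixture()
def stationary_stop_policy():
    """Stop-task responder with known true SSRT = 200 ms and tight go timing."""
    return ResponderPolicy("response_inhibition",
                           {"go_mean": 800.0, "go_sd": 50.0,
                            "ssrt_true": 200.0, "omission_rate": 0.0})


@pytest.fixture()
def mean_policies():
    return {d: make_policy(d, 0.0) for d in
            ("response_inhibition", "interference_control", "verbal_wm",
             "visuospatial_wm", "switching", "matching")}
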