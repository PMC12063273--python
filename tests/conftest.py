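import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    from gaitprop import load_params
    return load_params()


@pytest.fixture(scope="session")
def stroke_cohort(params):
    """One seeded metrics-mode stroke cohort, shared across tests."""
    from gaitprop import generate_cohort
    return generate_cohort(params, "stroke", 11)


@pytest.fixture(scope="session")
def stroke_table(stroke_cohort):
    from gaitprop import process_cohort
    table, _ = process_cohort(stroke_cohort)
    return table


@pytest.fixture(scope="session")
def control_cohort(params):
    from gaitprop import generate_cohort
    return generate_cohort(params, "control", 12)


@pytest.fixture(scope="session")
def control_table(control_cohort):
    from gaitprop import process_cohort
    table, _ = process_cohort(control_cohort)
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
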