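import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import dcismir as d  # noqa: E402


@pytest.fixture(scope="session")
def cohort():
    """The packaged 41-patient clinical table."""
    return d.load_example_cohort()


@pytest.fixture(scope="session")
def sim_reference():
    """Reference synthetic cohort: 32 samples, 300 miRNAs, 15 score-planted."""
    return d.simulate_all(d.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def norm_reference(sim_reference):
    return d.normalize_total_counts(sim_reference.counts)


@pytest.fixture(scope="session")
def sim_mixed():
    """Synthetic cohort with both score- and age-associated miRNAs."""
    return d.simulate_all(d.SimulationConfig(seed=3, n_score_assoc=9, n_age_assoc=6))
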