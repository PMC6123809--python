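import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient, 3-gene cohort reused by fast integration tests."""
    from utrscan.simulate import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig(seed=5, n_genes=3, n_patients=12))


@pytest.fixture(scope="session")
def standard_cohort():
    """The standard 290-patient, 6-gene cohort with the 12%-prevalence
    indel-dominant 3'-UTR hypermutation planted in gene G01."""
    from utrscan.simulate import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def standard_result(standard_cohort):
    from utrscan.pipeline import analyze_cohort

    return analyze_cohort(standard_cohort)
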