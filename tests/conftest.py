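import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=40,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """One patient per category, fixed seed."""
    from pumpsweep import generate_cohort
    return generate_cohort(42, 1)


@pytest.fixture(scope="session")
def adult(small_cohort):
    return small_cohort[2]


@pytest.fixture(scope="session")
def default_scenario():
    from pumpsweep import Scenario
    return Scenario()
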