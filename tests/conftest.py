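import pytest
from hypothesis import HealthCheck, settings

from weightbench import ActivityConfig, IntakeSchedule, Sex, SubjectProfile

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_female() -> SubjectProfile:
    """Reference participant: the cohort's typical female profile."""
    return SubjectProfile("ref-f", 46.0, Sex.FEMALE, 1.64, 112.1)


@pytest.fixture(scope="session")
def ref_male() -> SubjectProfile:
    return SubjectProfile("ref-m", 48.0, Sex.MALE, 1.77, 136.0)


@pytest.fixture(scope="session")
def program_schedule() -> IntakeSchedule:
    """1200 kcal/day in week 0, 900 kcal/day in weeks 1-7."""
    return IntakeSchedule.standard_program()


@pytest.fixture(scope="session")
def sedentary() -> ActivityConfig:
    return ActivityConfig(pal=1.4)
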