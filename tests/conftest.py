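import datetime as dt

import pytest

from adherepay import (
    CriteriaConfig,
    Participant,
    QCStatus,
    StudyConfig,
    WeighInEvent,
)

# Monday anchor so weekday arithmetic in tests is easy to read
MONDAY = dt.date(2023, 1, 9)
assert MONDAY.weekday() == 0


@pytest.fixture(scope="session")
def study_config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def criteria() -> CriteriaConfig:
    return CriteriaConfig()


@pytest.fixture(scope="session")
def tz(study_config):
    return study_config.tzinfo


@pytest.fixture(scope="session")
def participant() -> Participant:
    return Participant(
        participant_id="P001",
        sex="female",
        cohort=1,
        group=1,
        enrollment_date=MONDAY,
        status="active",
        scale_id="SC0001",
    )


def make_event(
    tz,
    pid="P001",
    day=0,
    hour=8,
    minute=0,
    weight=100.0,
    status=QCStatus.RAW,
    anchor=MONDAY,
):
    ts = dt.datetime.combine(
        anchor + dt.timedelta(days=day), dt.time(hour, minute), tzinfo=tz
    )
    return WeighInEvent(pid, ts, weight, status)


@pytest.fixture
def event_factory(tz):
    def factory(**kwargs):
        return make_event(tz, **kwargs)

    return factory
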