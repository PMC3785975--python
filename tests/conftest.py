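import datetime

import pytest

from alkcheck.assessment import ProgramBaseline, ScreeningRecord
from alkcheck import fixtures


def make_screening(**overrides) -> ScreeningRecord:
    base = dict(
        person_id="s0001",
        class_id="c01",
        gender="male",
        age_years=17,
        education="secondary",
        migration="none",
        smoking_item="occasional",
        activity_hours_week=4.0,
        rsod_category="3-4",
        drinking_calendar=(0, 0, 1, 0, 6, 8, 2),
        max_drinks_occasion=9,
        owns_mobile=True,
    )
    base.update(overrides)
    return ScreeningRecord(**base)


def make_baseline(**overrides) -> ProgramBaseline:
    base = dict(
        screening=make_screening(),
        problems=(True,) + (False,) * 9,
        importance_reduce="rather_unimportant",
        typical_drinking_day="friday",
        typical_drinking_time=datetime.time(21, 0),
    )
    base.update(overrides)
    return ProgramBaseline(**base)


@pytest.fixture
def screening_record():
    return make_screening()


@pytest.fixture
def program_baseline():
    return make_baseline()


@pytest.fixture(scope="session")
def flow_data():
    return fixtures.flow_fixture()


@pytest.fixture(scope="session")
def outcome_data():
    return fixtures.outcome_fixture()


@pytest.fixture(scope="session")
def program_use_data():
    return fixtures.program_use_fixture()
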