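import pytest

from anc_cea.synthetic import (
    eight_visit_schedule,
    four_visit_schedule,
    rwanda_attendance_scenarios,
    rwanda_reference_config,
)


@pytest.fixture(scope="session")
def four_visit():
    return four_visit_schedule()


@pytest.fixture(scope="session")
def eight_visit():
    return eight_visit_schedule()


@pytest.fixture(scope="session")
def scenarios():
    """{label: AttendanceScenario} for the Rwanda reference scenarios."""
    return {s.label: s for s in rwanda_attendance_scenarios()}


@pytest.fixture(scope="session")
def reference_config():
    return rwanda_reference_config(seed=1)
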