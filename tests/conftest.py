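import pytest
from hypothesis import settings

from fhscreen import decisions_frame, flowchart_fixture, run_screen

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic validation-study cohort (28,295 patients)."""
    return flowchart_fixture()


@pytest.fixture(scope="session")
def fixture_report(fixture_cohort):
    patients, labs = fixture_cohort
    return run_screen(patients, labs)


@pytest.fixture(scope="session")
def fixture_decisions(fixture_report, fixture_cohort):
    _, labs = fixture_cohort
    return decisions_frame(fixture_report, labs)
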