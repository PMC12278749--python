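import numpy as np
import pytest

from stopscore import canonical_stop_definition, make_fixture_124, records_to_frame


@pytest.fixture(scope="session")
def stop_definition():
    return canonical_stop_definition()


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 124-patient reference cohort: (scores, outcomes, records)."""
    return make_fixture_124()


@pytest.fixture(scope="session")
def fixture_frame(fixture_cohort):
    _, _, records = fixture_cohort
    return records_to_frame(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240 + 1)
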