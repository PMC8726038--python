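import pytest

from promtriage.instruments import (
    ASA,
    Charnley,
    CohortLabel,
    Instrument,
    PatientRecord,
    Timepoint,
    standard_items,
)
from promtriage.synthetic_cohort import make_paperlike_fixture
from promtriage.triage_engine import load_rule

FIXTURE_SEED = 20260927


@pytest.fixture(scope="session")
def defs():
    return standard_items()


@pytest.fixture(scope="session")
def rule9():
    return load_rule("candidate_9item")


@pytest.fixture(scope="session")
def rule6():
    return load_rule("final_6item")


@pytest.fixture(scope="session")
def paperlike():
    """Study-like training/test cohort pair (expensive; built once)."""
    return make_paperlike_fixture(FIXTURE_SEED)


def make_record(responses=None, returned=None, patient_id="P1", **kwargs):
    """A minimal valid patient record for unit tests."""
    fields = dict(
        patient_id=patient_id, surgery_year=2016,
        cohort_label=CohortLabel.TRAINING, age_years=66.0, gender="F",
        bmi_kg_m2=26.0, asa=ASA.I, charnley=Charnley.ONE_HIP,
    )
    fields.update(kwargs)
    rec = PatientRecord(**fields)
    rec.returned = returned if returned is not None else {
        Timepoint.PRE: True, Timepoint.M3: True, Timepoint.M12: True}
    if responses:
        for (instrument, idx, t), v in responses.items():
            rec.responses[(instrument, idx, t)] = v
    return rec
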