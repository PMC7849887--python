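import pytest

from dynascore.cohort import PatientRecord, to_frame
from dynascore.synthetic import CohortGenParams, generate_cohort


def make_record(
    patient_id="p1",
    sex="male",
    age=50,
    group="solitary_afl",
    followup_end=365,
    onset=None,
    af_day=None,
    stroke_day=None,
    prior_af=False,
    ablation=False,
    died=False,
):
    return PatientRecord(
        patient_id=patient_id,
        sex=sex,
        age_at_index=age,
        group=group,
        followup_end_day=followup_end,
        onset_day=dict(onset or {}),
        af_day=af_day,
        stroke_day=stroke_day,
        prior_af=prior_af,
        ablation_during_followup=ablation,
        died_during_followup=died,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-patient default-parameter cohort shared across tests."""
    return generate_cohort(CohortGenParams(n_per_group=300, seed=7))


@pytest.fixture(scope="session")
def small_frame(small_cohort):
    return to_frame(small_cohort)
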