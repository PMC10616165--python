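import numpy as np
import pandas as pd
import pytest

from neurocrit import (
    CohortSpec,
    DisabilityWeightMap,
    LifeTable,
    PatientRecord,
    PhysiologySnapshot,
    generate_cohort,
    generate_frame,
)


@pytest.fixture(scope="session")
def default_frame() -> pd.DataFrame:
    """Default synthetic cohort at the reference size, fixed seed."""
    return generate_frame(CohortSpec(n_patients=1194, seed=7))


@pytest.fixture(scope="session")
def small_records() -> list[PatientRecord]:
    return generate_cohort(CohortSpec(n_patients=200, seed=11))


def make_record(**overrides) -> PatientRecord:
    """A single valid record with convenient defaults for targeted edits."""
    base = dict(
        patient_id="P1",
        age=60,
        sex="male",
        diagnosis_group="TBI",
        insurance="public",
        admission_type="emergency",
        location_before_icu="emergency_department",
        gcs=9,
        apache2=14,
        saps3=47,
        sofa=5,
        comorbidities=frozenset({"hypertension"}),
        physiology=None,
        hs_flags=frozenset({"hypotension"}),
        outcome_status="icu_discharge",
        mrs=3,
        los_days=10,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture()
def record_factory():
    return make_record


NORMAL_PHYSIOLOGY = dict(
    map_mmHg=80.0,
    sbp_mmHg=120.0,
    pao2_mmHg=95.0,
    sao2_pct=97.0,
    spo2_pct=98.0,
    temp_C=36.8,
    paco2_mmHg=40.0,
    rr_ipm=16.0,
    glucose_mg_dL=100.0,
    sodium_mmol_L=140.0,
    icp_mmHg=10.0,
    herniation_clinical=False,
)


@pytest.fixture()
def normal_physiology() -> PhysiologySnapshot:
    return PhysiologySnapshot(**NORMAL_PHYSIOLOGY)


@pytest.fixture(scope="session")
def toy_life_table() -> LifeTable:
    """Flat-ish toy table with easy-to-hand-check values."""
    rows = []
    for sex, e18 in (("male", 55.0), ("female", 60.0)):
        for age in range(0, 111):
            rows.append({"sex": sex, "age": age, "ex": max(0.5, e18 - 0.5 * (age - 18))})
    return LifeTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def toy_weights() -> DisabilityWeightMap:
    return DisabilityWeightMap(
        mrs_weights={0: 0.0, 1: 0.1, 2: 0.2, 3: 0.3, 4: 0.4, 5: 0.5},
        comorbidity_weights={
            "hypertension": 0.1, "cardiopathy": 0.2, "copd": 0.3,
            "renal": 0.1, "diabetes": 0.1, "extracranial_neoplasia": 0.2,
        },
    )
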