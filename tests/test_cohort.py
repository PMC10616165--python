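"""Domain types, outcome coding, and the secondary-injury classifier."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocrit import PhysiologySnapshot, classify_hs, code_mortality, dichotomize_outcome
from neurocrit.cohort import (
    HS_FLAGS,
    DomainError,
    HsProfile,
    ValidationError,
    hs_category,
    resolve_hs,
)

from .conftest import NORMAL_PHYSIOLOGY, make_record


# --------------------------------------------------------------------------
# Outcome coding
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "mrs,expected",
    [(0, "favourable"), (1, "favourable"), (2, "favourable"), (3, "favourable"),
     (4, "unfavourable"), (5, "unfavourable"), (6, "unfavourable")],
)
def test_mrs_dichotomy(mrs, expected):
    assert dichotomize_outcome(mrs) == expected


@pytest.mark.parametrize("bad", [-1, 7, None, 3.5])
def test_mrs_out_of_domain(bad):
    with pytest.raises(DomainError):
        dichotomize_outcome(bad)


def test_mortality_pools_all_non_death_dispositions():
    # discharge + transfer + continued hospitalization together form the
    # survivor denominator (832 + 22 + 152 = 1006 in the reference cohort)
    assert code_mortality("death") == "death"
    for status in ("icu_discharge", "transfer", "continued_hospitalization"):
        assert code_mortality(status) == "non_death"
    assert 832 + 22 + 152 == 1006


# --------------------------------------------------------------------------
# Hs classifier
# --------------------------------------------------------------------------

def test_normal_snapshot_has_zero_flags(normal_physiology):
    profile = classify_hs(normal_physiology)
    assert profile.flags == frozenset()
    assert profile.count == 0 and profile.category == "zero"


def test_single_abnormality_map():
    p = PhysiologySnapshot(**{**NORMAL_PHYSIOLOGY, "map_mmHg": 60.0})
    profile = classify_hs(p)
    assert profile.flags == {"hypotension"}
    assert profile.category == "one"


def test_three_simultaneous_abnormalities():
    p = PhysiologySnapshot(**{**NORMAL_PHYSIOLOGY, "paco2_mmHg": 34.0, "temp_C": 34.5, "sodium_mmol_L": 130.0})
    profile = classify_hs(p)
    assert profile.flags == {"hypocapnia", "hypothermia", "hyponatremia"}
    assert profile.category == "three_plus"


@pytest.mark.parametrize(
    "field,value,flag",
    [
        ("map_mmHg", 65.0, "hypotension"),
        ("sbp_mmHg", 90.0, "hypotension"),
        ("pao2_mmHg", 60.0, "hypoxemia"),
        ("sao2_pct", 90.0, "hypoxemia"),
        ("spo2_pct", 90.0, "hypoxemia"),
        ("temp_C", 37.5, "hyperthermia"),
        ("temp_C", 35.0, "hypothermia"),
        ("paco2_mmHg", 45.0, "hypercapnia"),
        ("rr_ipm", 8.0, "hypercapnia"),
        ("paco2_mmHg", 35.0, "hypocapnia"),
        ("glucose_mg_dL", 60.0, "hypoglycaemia"),
        ("sodium_mmol_L", 135.0, "hyponatremia"),
        ("icp_mmHg", 25.0, "intracranial_hypertension"),
    ],
)
def test_equality_at_threshold_never_fires(field, value, flag):
    p = PhysiologySnapshot(**{**NORMAL_PHYSIOLOGY, field: value})
    assert flag not in classify_hs(p).flags


def test_missing_fields_never_fire():
    assert classify_hs(PhysiologySnapshot(glucose_mg_dL=50.0)).flags == {"hypoglycaemia"}


def test_all_missing_warns_and_returns_zero_profile():
    with pytest.warns(UserWarning, match="uninformative"):
        profile = classify_hs(PhysiologySnapshot())
    assert profile.count == 0


def test_herniation_is_recorded_not_computed(normal_physiology):
    p = dataclasses.replace(normal_physiology, herniation_clinical=True)
    assert classify_hs(p).flags == {"herniation"}


# Independent oracle: a literal re-statement of the ten threshold rules.
def _oracle_flags(p: PhysiologySnapshot) -> set[str]:
    f = set()
    def have(x):
        return x is not None
    if (have(p.map_mmHg) and p.map_mmHg < 65) or (have(p.sbp_mmHg) and p.sbp_mmHg < 90):
        f.add("hypotension")
    if (
        (have(p.pao2_mmHg) and p.pao2_mmHg < 60)
        or (have(p.sao2_pct) and p.sao2_pct < 90)
        or (have(p.spo2_pct) and p.spo2_pct < 90)
    ):
        f.add("hypoxemia")
    if have(p.temp_C) and p.temp_C > 37.5:
        f.add("hyperthermia")
    if (have(p.paco2_mmHg) and p.paco2_mmHg > 45) or (have(p.rr_ipm) and p.rr_ipm < 8):
        f.add("hypercapnia")
    if have(p.paco2_mmHg) and p.paco2_mmHg < 35:
        f.add("hypocapnia")
    if have(p.glucose_mg_dL) and p.glucose_mg_dL < 60:
        f.add("hypoglycaemia")
    if have(p.sodium_mmol_L) and p.sodium_mmol_L < 135:
        f.add("hyponatremia")
    if have(p.temp_C) and p.temp_C < 35:
        f.add("hypothermia")
    if have(p.icp_mmHg) and p.icp_mmHg > 25:
        f.add("intracranial_hypertension")
    if p.herniation_clinical:
        f.add("herniation")
    return f


_BOUNDARYISH = {
    "map_mmHg": (40.0, 65.0, 110.0),
    "sbp_mmHg": (60.0, 90.0, 150.0),
    "pao2_mmHg": (40.0, 60.0, 120.0),
    "sao2_pct": (80.0, 90.0, 100.0),
    "spo2_pct": (80.0, 90.0, 100.0),
    "temp_C": (30.0, 35.0, 36.5, 37.5, 41.0),
    "paco2_mmHg": (25.0, 35.0, 40.0, 45.0, 60.0),
    "rr_ipm": (4.0, 8.0, 20.0),
    "glucose_mg_dL": (30.0, 60.0, 150.0),
    "sodium_mmol_L": (120.0, 135.0, 145.0),
    "icp_mmHg": (5.0, 25.0, 40.0),
}


def _snapshot_strategy():
    def field_strategy(name):
        lo, *_, hi = _BOUNDARYISH[name]
        return st.one_of(
            st.none(),
            st.sampled_from(_BOUNDARYISH[name]),
            st.floats(min_value=lo, max_value=hi, allow_nan=False),
        )

    return st.builds(
        PhysiologySnapshot,
        **{name: field_strategy(name) for name in _BOUNDARYISH},
        herniation_clinical=st.booleans(),
    )


@given(_snapshot_strategy())
@settings(max_examples=500, deadline=None, derandomize=True)
def test_classifier_matches_brute_force_oracle(snapshot):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert set(classify_hs(snapshot).flags) == _oracle_flags(snapshot)


@given(_snapshot_strategy(), st.sampled_from(sorted(_BOUNDARYISH)))
@settings(max_examples=300, deadline=None, derandomize=True)
def test_classifier_monotone_in_each_measurement(snapshot, field):
    """Pushing one measurement further past its threshold never clears a flag."""
    import warnings

    value = getattr(snapshot, field)
    if value is None:
        return
    # direction of "more abnormal" per field rule (temp/paco2 have two-sided rules;
    # move away from the normal band in the direction already taken)
    lower_is_worse = {
        "map_mmHg", "sbp_mmHg", "pao2_mmHg", "sao2_pct", "spo2_pct",
        "rr_ipm", "glucose_mg_dL", "sodium_mmol_L",
    }
    if field in lower_is_worse:
        worse = value - 5.0
    elif field == "icp_mmHg":
        worse = value + 5.0
    elif field == "temp_C":
        worse = value - 1.0 if value < 36.25 else value + 1.0
        worse = min(max(worse, 25.0), 45.0)
    else:  # paco2: below 40 -> lower is worse (hypocapnia), above -> higher (hypercapnia)
        worse = value - 5.0 if value < 40 else value + 5.0
    if field in ("sao2_pct", "spo2_pct"):
        worse = max(worse, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        before = classify_hs(snapshot).flags
        after = classify_hs(dataclasses.replace(snapshot, **{field: worse})).flags
    assert before <= after


# --------------------------------------------------------------------------
# Profiles / record validation
# --------------------------------------------------------------------------

def test_hs_category_partition():
    assert [hs_category(c) for c in range(11)] == (
        ["zero", "one", "two"] + ["three_plus"] * 8
    )


def test_hs_profile_count_matches_flags():
    p = HsProfile(flags=frozenset({"hypotension", "herniation"}))
    assert p.count == 2 and p.category == "two"
    with pytest.raises(ValidationError):
        HsProfile(flags=frozenset({"not_a_flag"}))


def test_death_mrs_consistency_enforced():
    with pytest.raises(ValidationError, match="inconsistent"):
        make_record(outcome_status="icu_discharge", mrs=6)
    with pytest.raises(ValidationError, match="inconsistent"):
        make_record(outcome_status="death", mrs=3)
    make_record(outcome_status="death", mrs=6)  # consistent: fine
    make_record(outcome_status="death", mrs=None)  # mRS unrecorded: fine


@pytest.mark.parametrize(
    "overrides",
    [
        {"age": 17},
        {"sex": "unknown"},
        {"gcs": 16},
        {"sofa": 25},
        {"los_days": 31},
        {"comorbidities": frozenset({"asthma"})},
        {"diagnosis_group": "stroke"},
    ],
)
def test_invalid_field_values_rejected(overrides):
    with pytest.raises(ValidationError):
        make_record(**overrides)


def test_physiology_and_flags_must_agree(normal_physiology):
    with pytest.raises(ValidationError, match="disagree"):
        make_record(physiology=normal_physiology, hs_flags=frozenset({"hypotension"}))
    r = make_record(physiology=normal_physiology, hs_flags=frozenset())
    assert resolve_hs(r).count == 0


def test_resolve_hs_requires_some_source():
    r = make_record(physiology=None, hs_flags=None)
    with pytest.raises(DomainError):
        resolve_hs(r)


def test_snapshot_range_validation():
    with pytest.raises(ValidationError):
        PhysiologySnapshot(temp_C=50.0)
    with pytest.raises(ValidationError):
        PhysiologySnapshot(spo2_pct=120.0)
    with pytest.raises(ValidationError):
        PhysiologySnapshot(map_mmHg=float("nan"))
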