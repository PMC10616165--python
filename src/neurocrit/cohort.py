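"""Patient-level domain types, outcome coding, and the secondary-injury classifier.

A neurocritical-care admission is represented by :class:`PatientRecord`:
demographics, the primary acute neurological diagnosis (one of ten groups),
severity scores at ICU admission (GCS, APACHE II, SAPS III, SOFA), first-24 h
physiology, comorbidities, and the 30-day outcome (ICU disposition, modified
Rankin Scale, length of stay).

Ten potential secondary brain injuries — the "Hs" — are defined by threshold
rules on admission physiology (hypotension, hypoxemia, hyperthermia,
hypercapnia, hypocapnia, hypoglycaemia, hyponatremia, hypothermia,
intracranial hypertension, and clinical herniation).  :func:`classify_hs`
applies those rules; all inequalities are strict, and a missing measurement
never fires a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields

__all__ = [
    "DIAGNOSIS_GROUPS",
    "COMORBIDITIES",
    "HS_FLAGS",
    "HS_CATEGORIES",
    "OUTCOME_STATUSES",
    "ValidationError",
    "DomainError",
    "PhysiologySnapshot",
    "HsProfile",
    "PatientRecord",
    "classify_hs",
    "hs_category",
    "resolve_hs",
    "dichotomize_outcome",
    "code_mortality",
]

DIAGNOSIS_GROUPS = (
    "NPO",       # postoperative care of elective neurosurgery
    "TBI",       # traumatic brain injury
    "IS",        # ischaemic stroke
    "ENC",       # encephalopathy
    "seizures",
    "ICH",       # intracerebral haemorrhage
    "SAH",       # subarachnoid haemorrhage
    "SNI",       # central nervous system infection
    "SCI",       # spinal cord injury
    "NMD",       # neuromuscular disease
)

COMORBIDITIES = (
    "hypertension",
    "cardiopathy",
    "copd",
    "renal",
    "diabetes",
    "extracranial_neoplasia",
)

HS_FLAGS = (
    "hypotension",
    "hypoxemia",
    "hyperthermia",
    "hypercapnia",
    "hypocapnia",
    "hypoglycaemia",
    "hyponatremia",
    "hypothermia",
    "intracranial_hypertension",
    "herniation",
)

HS_CATEGORIES = ("zero", "one", "two", "three_plus")

OUTCOME_STATUSES = ("icu_discharge", "transfer", "continued_hospitalization", "death")

SEXES = ("male", "female")
INSURANCES = ("public", "private")
ADMISSION_TYPES = ("elective", "emergency")
LOCATIONS = ("emergency_department", "operating_room", "ward", "other")


class ValidationError(ValueError):
    """A record or snapshot violates a domain invariant."""


class DomainError(ValueError):
    """An operation was called with an argument outside its domain."""


def _check_finite(name: str, value: float | None) -> None:
    if value is not None and not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class PhysiologySnapshot:
    """Worst first-24 h physiology used for Hs classification.

    Every numeric field is optional; ``None`` means "not assessed" and is never
    imputed.  Saturations are percentages in [0, 100]; temperature must lie in a
    plausible clinical range (25–45 °C).  Out-of-range values raise
    :class:`ValidationError` rather than being clamped.
    """

    map_mmHg: float | None = None
    sbp_mmHg: float | None = None
    pao2_mmHg: float | None = None
    sao2_pct: float | None = None
    spo2_pct: float | None = None
    temp_C: float | None = None
    paco2_mmHg: float | None = None
    rr_ipm: float | None = None
    glucose_mg_dL: float | None = None
    sodium_mmol_L: float | None = None
    icp_mmHg: float | None = None
    herniation_clinical: bool = False

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "herniation_clinical":
                continue
            _check_finite(f.name, getattr(self, f.name))
        for name in ("sao2_pct", "spo2_pct"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} must be in [0, 100], got {v}")
        if self.temp_C is not None and not 25.0 <= self.temp_C <= 45.0:
            raise ValidationError(f"temp_C must be in [25, 45], got {self.temp_C}")

    def all_missing(self) -> bool:
        return all(
            getattr(self, f.name) is None
            for f in fields(self)
            if f.name != "herniation_clinical"
        )


def hs_category(count: int) -> str:
    """Partition an Hs count into the categories {0}, {1}, {2}, {>=3}."""
    if not 0 <= count <= len(HS_FLAGS):
        raise DomainError(f"Hs count must be in 0..{len(HS_FLAGS)}, got {count}")
    if count >= 3:
        return "three_plus"
    return HS_CATEGORIES[count]


@dataclass(frozen=True)
class HsProfile:
    """The set of secondary injuries present, its size, and its category."""

    flags: frozenset[str]
    count: int = field(init=False)
    category: str = field(init=False)

    def __post_init__(self) -> None:
        unknown = set(self.flags) - set(HS_FLAGS)
        if unknown:
            raise ValidationError(f"unknown Hs flags: {sorted(unknown)}")
        object.__setattr__(self, "flags", frozenset(self.flags))
        object.__setattr__(self, "count", len(self.flags))
        object.__setattr__(self, "category", hs_category(len(self.flags)))


# Threshold rules: flag fires iff any listed (field, direction, cutoff)
# comparison holds STRICTLY.  Equality at a cutoff is negative by design.
_HS_RULES: dict[str, tuple[tuple[str, str, float], ...]] = {
    "hypotension": (("map_mmHg", "<", 65.0), ("sbp_mmHg", "<", 90.0)),
    "hypoxemia": (("pao2_mmHg", "<", 60.0), ("sao2_pct", "<", 90.0), ("spo2_pct", "<", 90.0)),
    "hyperthermia": (("temp_C", ">", 37.5),),
    "hypercapnia": (("paco2_mmHg", ">", 45.0), ("rr_ipm", "<", 8.0)),
    "hypocapnia": (("paco2_mmHg", "<", 35.0),),
    "hypoglycaemia": (("glucose_mg_dL", "<", 60.0),),
    "hyponatremia": (("sodium_mmol_L", "<", 135.0),),
    "hypothermia": (("temp_C", "<", 35.0),),
    "intracranial_hypertension": (("icp_mmHg", ">", 25.0),),
}


def classify_hs(p: PhysiologySnapshot) -> HsProfile:
    """Apply the ten secondary-injury threshold rules to a physiology snapshot.

    A flag fires only on an observed value strictly beyond its cutoff
    (e.g. hypotension: MAP < 65 mmHg or SBP < 90 mmHg); missing fields never
    fire.  Herniation is a recorded clinical finding, taken as-is.  A snapshot
    with no physiology at all and no herniation yields a zero-flag profile with
    an "uninformative input" warning.
    """
    if p.all_missing() and not p.herniation_clinical:
        warnings.warn(
            "uninformative input: all physiology missing and no herniation; "
            "returning a zero-flag profile",
            stacklevel=2,
        )
        return HsProfile(flags=frozenset())

    flags = set()
    for flag, rules in _HS_RULES.items():
        for field_name, op, cutoff in rules:
            v = getattr(p, field_name)
            if v is None:
                continue
            if (op == "<" and v < cutoff) or (op == ">" and v > cutoff):
                flags.add(flag)
                break
    if p.herniation_clinical:
        flags.add("herniation")
    return HsProfile(flags=frozenset(flags))


def dichotomize_outcome(mrs: int) -> str:
    """Code a modified Rankin Scale score: 4, 5 or 6 is unfavourable; 0–3 favourable."""
    if mrs is None or mrs not in range(7):
        raise DomainError(f"mRS must be an integer in 0..6, got {mrs!r}")
    return "unfavourable" if mrs >= 4 else "favourable"


def code_mortality(outcome_status: str) -> str:
    """Code the 30-day ICU disposition as death vs non-death.

    Non-death pools ICU discharge, transfer to another hospital, and continued
    hospitalization at day 30 — the three dispositions that together form the
    survivor denominator of the unadjusted odds-ratio tables.
    """
    if outcome_status not in OUTCOME_STATUSES:
        raise DomainError(f"unknown outcome_status {outcome_status!r}")
    return "death" if outcome_status == "death" else "non_death"


@dataclass
class PatientRecord:
    """One validated neurocritical-care admission.

    Invariants enforced on construction: death and mRS 6 imply each other when
    mRS is recorded; length of stay is capped by the 30-day follow-up window;
    category fields take only their documented levels; when both physiology and
    precomputed Hs flags are present they must agree under :func:`classify_hs`.
    """

    patient_id: str
    age: int
    sex: str
    diagnosis_group: str
    insurance: str
    admission_type: str
    location_before_icu: str
    gcs: int
    apache2: int
    saps3: int | None
    sofa: int | None
    comorbidities: frozenset[str]
    outcome_status: str
    mrs: int | None
    los_days: int
    physiology: PhysiologySnapshot | None = None
    hs_flags: frozenset[str] | None = None

    def __post_init__(self) -> None:
        pid = self.patient_id
        if not isinstance(pid, str) or not pid:
            raise ValidationError(f"patient_id must be a non-empty string, got {pid!r}")
        if not isinstance(self.age, int) or self.age < 18:
            raise ValidationError(f"[{pid}] age must be an integer >= 18, got {self.age!r}")
        for name, value, levels in (
            ("sex", self.sex, SEXES),
            ("diagnosis_group", self.diagnosis_group, DIAGNOSIS_GROUPS),
            ("insurance", self.insurance, INSURANCES),
            ("admission_type", self.admission_type, ADMISSION_TYPES),
            ("location_before_icu", self.location_before_icu, LOCATIONS),
            ("outcome_status", self.outcome_status, OUTCOME_STATUSES),
        ):
            if value not in levels:
                raise ValidationError(f"[{pid}] invalid {name} {value!r}; expected one of {levels}")
        if not isinstance(self.gcs, int) or not 3 <= self.gcs <= 15:
            raise ValidationError(f"[{pid}] gcs must be an integer in 3..15, got {self.gcs!r}")
        if not isinstance(self.apache2, int) or self.apache2 < 0:
            raise ValidationError(f"[{pid}] apache2 must be a non-negative integer, got {self.apache2!r}")
        if self.saps3 is not None and (not isinstance(self.saps3, int) or self.saps3 < 0):
            raise ValidationError(f"[{pid}] saps3 must be a non-negative integer or missing, got {self.saps3!r}")
        if self.sofa is not None and (not isinstance(self.sofa, int) or not 0 <= self.sofa <= 24):
            raise ValidationError(f"[{pid}] sofa must be an integer in 0..24 or missing, got {self.sofa!r}")
        self.comorbidities = frozenset(self.comorbidities)
        unknown = self.comorbidities - set(COMORBIDITIES)
        if unknown:
            raise ValidationError(f"[{pid}] unknown comorbidities: {sorted(unknown)}")
        if self.mrs is not None and (not isinstance(self.mrs, int) or not 0 <= self.mrs <= 6):
            raise ValidationError(f"[{pid}] mrs must be an integer in 0..6 or missing, got {self.mrs!r}")
        if self.mrs is not None:
            if (self.outcome_status == "death") != (self.mrs == 6):
                raise ValidationError(
                    f"[{pid}] outcome_status {self.outcome_status!r} inconsistent with mrs {self.mrs}"
                )
        if not isinstance(self.los_days, int) or not 0 <= self.los_days <= 30:
            raise ValidationError(f"[{pid}] los_days must be an integer in 0..30, got {self.los_days!r}")
        if self.hs_flags is not None:
            self.hs_flags = frozenset(self.hs_flags)
            unknown = self.hs_flags - set(HS_FLAGS)
            if unknown:
                raise ValidationError(f"[{pid}] unknown hs flags: {sorted(unknown)}")
        if self.physiology is not None and self.hs_flags is not None:
            derived = classify_hs(self.physiology).flags
            if derived != self.hs_flags:
                raise ValidationError(
                    f"[{pid}] recorded hs_flags {sorted(self.hs_flags)} disagree with "
                    f"physiology-derived flags {sorted(derived)}"
                )

    @property
    def died(self) -> bool:
        return self.outcome_status == "death"


def resolve_hs(record: PatientRecord) -> HsProfile:
    """Resolve a record's Hs profile from recorded flags or, failing that, physiology."""
    if record.hs_flags is not None:
        return HsProfile(flags=record.hs_flags)
    if record.physiology is not None:
        return classify_hs(record.physiology)
    raise DomainError(
        f"[{record.patient_id}] neither hs_flags nor physiology available; "
        "cannot resolve secondary injuries"
    )
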