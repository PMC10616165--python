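"""Cohort CSV input/output and DataFrame conversion.

The on-disk schema is a flat, comma-separated, UTF-8 table with "." as the
decimal mark, lowercase snake_case headers, and an empty cell for a missing
value.  Booleans are written as ``1``/``0``.  ``write_cohort`` followed by
``read_cohort`` reproduces every field bit-exactly.

Columns, in order: patient_id, age, sex, diagnosis_group, insurance,
admission_type, location_before_icu, gcs, apache2, saps3, sofa, the six
comorbidity flags, the twelve physiology fields, the ten optional ``hs_*``
flags, outcome_status, mrs, los_days.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import pandas as pd

from .cohort import (
    COMORBIDITIES,
    HS_FLAGS,
    PatientRecord,
    PhysiologySnapshot,
    ValidationError,
    dichotomize_outcome,
    resolve_hs,
)

__all__ = ["SchemaError", "COHORT_COLUMNS", "read_cohort", "write_cohort", "cohort_to_frame"]


class SchemaError(ValueError):
    """The file header does not match the documented cohort schema."""


_PHYS_NUMERIC = (
    "map_mmhg",
    "sbp_mmhg",
    "pao2_mmhg",
    "sao2_pct",
    "spo2_pct",
    "temp_c",
    "paco2_mmhg",
    "rr_ipm",
    "glucose_mg_dl",
    "sodium_mmol_l",
    "icp_mmhg",
)

# CSV column -> PhysiologySnapshot attribute
_PHYS_ATTR = {
    "map_mmhg": "map_mmHg",
    "sbp_mmhg": "sbp_mmHg",
    "pao2_mmhg": "pao2_mmHg",
    "sao2_pct": "sao2_pct",
    "spo2_pct": "spo2_pct",
    "temp_c": "temp_C",
    "paco2_mmhg": "paco2_mmHg",
    "rr_ipm": "rr_ipm",
    "glucose_mg_dl": "glucose_mg_dL",
    "sodium_mmol_l": "sodium_mmol_L",
    "icp_mmhg": "icp_mmHg",
}

COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age",
    "sex",
    "diagnosis_group",
    "insurance",
    "admission_type",
    "location_before_icu",
    "gcs",
    "apache2",
    "saps3",
    "sofa",
    *COMORBIDITIES,
    *_PHYS_NUMERIC,
    "herniation_clinical",
    *(f"hs_{f}" for f in HS_FLAGS),
    "outcome_status",
    "mrs",
    "los_days",
)


def _opt_int(cell: str) -> int | None:
    return None if cell == "" else int(cell)


def _opt_float(cell: str) -> float | None:
    return None if cell == "" else float(cell)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _row_to_record(row: dict[str, str], index: int) -> PatientRecord:
    phys_cells = {c: row[c] for c in _PHYS_NUMERIC}
    herniation_cell = row["herniation_clinical"]
    if all(v == "" for v in phys_cells.values()) and herniation_cell == "":
        physiology = None
    else:
        physiology = PhysiologySnapshot(
            herniation_clinical=(herniation_cell == "1"),
            **{_PHYS_ATTR[c]: _opt_float(v) for c, v in phys_cells.items()},
        )
    hs_cells = {f: row[f"hs_{f}"] for f in HS_FLAGS}
    if all(v == "" for v in hs_cells.values()):
        hs_flags = None
    else:
        hs_flags = frozenset(f for f, v in hs_cells.items() if v == "1")
    return PatientRecord(
        patient_id=row["patient_id"],
        age=int(row["age"]),
        sex=row["sex"],
        diagnosis_group=row["diagnosis_group"],
        insurance=row["insurance"],
        admission_type=row["admission_type"],
        location_before_icu=row["location_before_icu"],
        gcs=int(row["gcs"]),
        apache2=int(row["apache2"]),
        saps3=_opt_int(row["saps3"]),
        sofa=_opt_int(row["sofa"]),
        comorbidities=frozenset(c for c in COMORBIDITIES if row[c] == "1"),
        physiology=physiology,
        hs_flags=hs_flags,
        outcome_status=row["outcome_status"],
        mrs=_opt_int(row["mrs"]),
        los_days=int(row["los_days"]),
    )


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read and validate a cohort CSV, returning one record per row.

    Raises :class:`SchemaError` if a mandatory column is absent, and
    :class:`~neurocrit.cohort.ValidationError` listing every failing row
    (1-based data-row index) if any row violates an invariant.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in COHORT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns {missing}")
        records: list[PatientRecord] = []
        problems: list[str] = []
        for i, row in enumerate(reader, start=1):
            try:
                records.append(_row_to_record(row, i))
            except (ValidationError, ValueError) as exc:
                problems.append(f"row {i}: {exc}")
    if problems:
        raise ValidationError(f"{path}: {len(problems)} invalid rows:\n" + "\n".join(problems))
    return records


def _record_to_row(r: PatientRecord) -> list[str]:
    p = r.physiology
    phys = ["" for _ in _PHYS_NUMERIC] + [""]
    if p is not None:
        phys = [_fmt(getattr(p, _PHYS_ATTR[c])) for c in _PHYS_NUMERIC]
        phys.append(_fmt(p.herniation_clinical))
    if r.hs_flags is None:
        hs = ["" for _ in HS_FLAGS]
    else:
        hs = [_fmt(f in r.hs_flags) for f in HS_FLAGS]
    return [
        r.patient_id,
        _fmt(r.age),
        r.sex,
        r.diagnosis_group,
        r.insurance,
        r.admission_type,
        r.location_before_icu,
        _fmt(r.gcs),
        _fmt(r.apache2),
        _fmt(r.saps3),
        _fmt(r.sofa),
        *(_fmt(c in r.comorbidities) for c in COMORBIDITIES),
        *phys,
        *hs,
        r.outcome_status,
        _fmt(r.mrs),
        _fmt(r.los_days),
    ]


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records to a cohort CSV in the documented schema (header always present)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow(_record_to_row(r))


def cohort_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Flatten records into the analysis DataFrame used by the modelling layers.

    Adds derived columns: ``died`` (bool), ``unfavourable`` (nullable bool,
    missing when mRS is missing), ``hs_count`` and ``hs_category`` (resolved
    from recorded flags or physiology).
    """
    rows = []
    for r in records:
        profile = resolve_hs(r)
        rows.append(
            {
                "patient_id": r.patient_id,
                "age": r.age,
                "sex": r.sex,
                "male": r.sex == "male",
                "diagnosis_group": r.diagnosis_group,
                "insurance": r.insurance,
                "public": r.insurance == "public",
                "admission_type": r.admission_type,
                "emergency": r.admission_type == "emergency",
                "location_before_icu": r.location_before_icu,
                "gcs": r.gcs,
                "apache2": r.apache2,
                "saps3": r.saps3,
                "sofa": r.sofa,
                **{c: c in r.comorbidities for c in COMORBIDITIES},
                "hs_count": profile.count,
                "hs_category": profile.category,
                "outcome_status": r.outcome_status,
                "died": r.died,
                "mrs": r.mrs,
                "unfavourable": None if r.mrs is None else dichotomize_outcome(r.mrs) == "unfavourable",
                "los_days": r.los_days,
            }
        )
    columns = [
        "patient_id", "age", "sex", "male", "diagnosis_group", "insurance", "public",
        "admission_type", "emergency", "location_before_icu", "gcs", "apache2",
        "saps3", "sofa", *COMORBIDITIES, "hs_count", "hs_category",
        "outcome_status", "died", "mrs", "unfavourable", "los_days",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    frame["saps3"] = frame["saps3"].astype("Int64")
    frame["sofa"] = frame["sofa"].astype("Int64")
    frame["mrs"] = frame["mrs"].astype("Int64")
    frame["unfavourable"] = frame["unfavourable"].astype("boolean")
    return frame
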