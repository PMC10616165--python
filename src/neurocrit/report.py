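"""Cohort report tables: descriptive summary and unadjusted odds ratios.

Shapes mirror the descriptive and univariate tables of a multicentre ICU
cohort report: categorical rows as n (%) within column, skewed scores as
median (IQR), age as mean +/- SD, and per-factor unadjusted ORs with Wald
95% CIs for both study outcomes.  Print precision is frozen (percentages to
1 decimal, ORs and CIs to 3) so golden-file comparisons are meaningful.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import COMORBIDITIES, DIAGNOSIS_GROUPS, HS_CATEGORIES
from .stats import DegenerateTableError, TwoByTwo, fit_logistic, odds_ratio

__all__ = ["report_descriptives", "report_univariate", "to_markdown"]

log = logging.getLogger("neurocrit")


def _cat_rows(section: str, series: pd.Series, levels, n_total: int) -> list[dict]:
    rows = []
    for level in levels:
        k = int((series == level).sum())
        rows.append(
            {
                "section": section, "row": str(level), "kind": "categorical",
                "n": k, "pct": round(100.0 * k / n_total, 1),
                "median": None, "q1": None, "q3": None, "mean": None, "sd": None,
                "n_missing": int(series.isna().sum()),
            }
        )
    return rows


def _median_row(section: str, row: str, series: pd.Series) -> dict:
    s = series.dropna().astype(float)
    if s.empty:
        log.warning("descriptives: column %r empty; row suppressed", row)
        return {}
    return {
        "section": section, "row": row, "kind": "median_iqr",
        "n": int(s.size), "pct": None,
        "median": float(s.median()), "q1": float(s.quantile(0.25)), "q3": float(s.quantile(0.75)),
        "mean": None, "sd": None, "n_missing": int(series.isna().sum()),
    }


def _mean_row(section: str, row: str, series: pd.Series) -> dict:
    s = series.dropna().astype(float)
    return {
        "section": section, "row": row, "kind": "mean_sd",
        "n": int(s.size), "pct": None, "median": None, "q1": None, "q3": None,
        "mean": float(s.mean()), "sd": float(s.std(ddof=1)),
        "n_missing": int(series.isna().sum()),
    }


def report_descriptives(frame: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary of a cohort frame, one tidy row per table line."""
    n = len(frame)
    rows: list[dict] = [_mean_row("baseline", "age", frame["age"])]
    rows += _cat_rows("baseline", frame["sex"], ("male", "female"), n)
    rows += _cat_rows("insurance", frame["insurance"], ("public", "private"), n)
    rows += _cat_rows("admission_type", frame["admission_type"], ("elective", "emergency"), n)
    rows += _cat_rows(
        "location_before_icu", frame["location_before_icu"],
        ("emergency_department", "operating_room", "ward", "other"), n,
    )
    for score in ("gcs", "apache2", "saps3", "sofa"):
        r = _median_row("severity", score, frame[score])
        if r:
            rows.append(r)
    for c in COMORBIDITIES:
        k = int(frame[c].sum())
        rows.append(
            {
                "section": "comorbidities", "row": c, "kind": "categorical",
                "n": k, "pct": round(100.0 * k / n, 1),
                "median": None, "q1": None, "q3": None, "mean": None, "sd": None,
                "n_missing": 0,
            }
        )
    rows += _cat_rows("diagnosis_group", frame["diagnosis_group"], DIAGNOSIS_GROUPS, n)
    rows += _cat_rows("hs_category", frame["hs_category"], HS_CATEGORIES, n)
    rows += _cat_rows(
        "outcome_status", frame["outcome_status"],
        ("icu_discharge", "transfer", "continued_hospitalization", "death"), n,
    )
    rows += _cat_rows("mrs", frame["mrs"], tuple(range(7)), n)
    unf = frame["unfavourable"]
    rows.append(
        {
            "section": "outcome", "row": "unfavourable", "kind": "categorical",
            "n": int((unf == True).sum()),  # noqa: E712  (nullable boolean)
            "pct": round(100.0 * int((unf == True).sum()) / n, 1),  # noqa: E712
            "median": None, "q1": None, "q3": None, "mean": None, "sd": None,
            "n_missing": int(unf.isna().sum()),
        }
    )
    r = _median_row("outcome", "los_days", frame["los_days"])
    if r:
        rows.append(r)
    return pd.DataFrame([r for r in rows if r])


_CATEGORICAL_FACTORS = (
    # (factor, exposed level, reference level, column)
    ("sex", "male", "female", "sex"),
    ("hs_category", "one", "zero", "hs_category"),
    ("hs_category", "two", "zero", "hs_category"),
    ("hs_category", "three_plus", "zero", "hs_category"),
    ("insurance", "public", "private", "insurance"),
    ("admission_type", "emergency", "elective", "admission_type"),
)

_CONTINUOUS_FACTORS = ("age", "gcs", "apache2", "saps3", "sofa")


def _outcome_mask(frame: pd.DataFrame, outcome: str) -> tuple[pd.Series, np.ndarray]:
    if outcome == "mortality":
        return frame["died"].astype(bool), np.ones(len(frame), dtype=bool)
    unf = frame["unfavourable"]
    return unf.fillna(False).astype(bool), unf.notna().to_numpy()


def report_univariate(frame: pd.DataFrame) -> pd.DataFrame:
    """Unadjusted OR table for both outcomes (2x2 for categorical factors,
    per-unit univariate logistic for continuous scores).

    Degenerate strata (an absent level, a zero cell) are kept as flagged rows
    with missing estimates rather than silently dropped.
    """
    out_rows = []
    for outcome in ("mortality", "unfavourable"):
        y, valid = _outcome_mask(frame, outcome)
        for factor, exposed, ref, col in _CATEGORICAL_FACTORS:
            is_exp = (frame[col] == exposed).to_numpy() & valid
            is_ref = (frame[col] == ref).to_numpy() & valid
            yv = y.to_numpy()
            row = {
                "outcome": outcome, "factor": factor,
                "level": f"{exposed} vs {ref}", "per_unit": False,
                "events_exposed": int(yv[is_exp].sum()), "n_exposed": int(is_exp.sum()),
                "events_ref": int(yv[is_ref].sum()), "n_ref": int(is_ref.sum()),
                "or_": None, "ci_low": None, "ci_high": None, "p_wald": None,
                "flag": "",
            }
            try:
                t = TwoByTwo(
                    exposed_events=row["events_exposed"],
                    exposed_nonevents=row["n_exposed"] - row["events_exposed"],
                    ref_events=row["events_ref"],
                    ref_nonevents=row["n_ref"] - row["events_ref"],
                )
                res = odds_ratio(t)
                row.update(or_=res.or_point, ci_low=res.ci_low, ci_high=res.ci_high, p_wald=res.p_wald)
            except (DegenerateTableError, ValueError) as exc:
                row["flag"] = f"degenerate: {exc}"
                log.warning("univariate %s/%s: %s", outcome, factor, exc)
            out_rows.append(row)
        for col in _CONTINUOUS_FACTORS:
            x = frame[col].astype("Float64").astype(float)
            keep = valid & x.notna().to_numpy()
            row = {
                "outcome": outcome, "factor": col, "level": "per unit", "per_unit": True,
                "events_exposed": int(y.to_numpy()[keep].sum()), "n_exposed": int(keep.sum()),
                "events_ref": None, "n_ref": None,
                "or_": None, "ci_low": None, "ci_high": None, "p_wald": None,
                "flag": "",
            }
            try:
                fit = fit_logistic(pd.DataFrame({col: x[keep]}), y.to_numpy()[keep].astype(float))
                est = fit.table.loc[col]
                row.update(
                    or_=float(est["or_"]), ci_low=float(est["ci_low"]),
                    ci_high=float(est["ci_high"]), p_wald=float(est["p_wald"]),
                )
            except (ValueError, RuntimeError) as exc:
                row["flag"] = f"degenerate: {exc}"
                log.warning("univariate %s/%s: %s", outcome, col, exc)
            out_rows.append(row)
    return pd.DataFrame(out_rows)


def to_markdown(table: pd.DataFrame, float_cols_3dp: tuple[str, ...] = ("or_", "ci_low", "ci_high")) -> str:
    """Fixed-precision markdown rendering (ORs/CIs to 3 decimals, percents to 1)."""
    t = table.copy()
    for c in t.columns:
        if c in float_cols_3dp:
            t[c] = t[c].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
        elif c in ("pct",):
            t[c] = t[c].map(lambda v: "" if pd.isna(v) else f"{v:.1f}")
        elif c in ("p_wald",):
            t[c] = t[c].map(lambda v: "" if pd.isna(v) else ("<0.001" if v < 0.001 else f"{v:.3f}"))
        elif t[c].dtype == float:
            t[c] = t[c].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    t = t.fillna("")
    header = "| " + " | ".join(t.columns) + " |"
    sep = "|" + "|".join("---" for _ in t.columns) + "|"
    body = ["| " + " | ".join(str(v) for v in row) + " |" for row in t.itertuples(index=False)]
    return "\n".join([header, sep, *body]) + "\n"
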