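"""Disease-burden engine: life-table YLL, disability-weighted YLD, DALYs.

DALY = YLL + YLD.  Each ICU death contributes the residual life expectancy
``e_x`` at its age and sex, read from a complete (single-year) life table.
Each survivor contributes a disability weight selected by 30-day mRS level,
combined with the weights of the patient's chronic comorbidities by the
multiplicative complement ``1 - prod(1 - w)`` (the Global Burden of Disease
comorbidity-correction convention; the raw product is available for
sensitivity analysis), times a prevalence scaling and a time horizon in
years.  No age-weighting and no time-discounting are applied.

Population prevalence by diagnosis, sex and 5-year age band is estimated by
a transparent beta-binomial shrinkage estimator.  This is a deliberately
simple, reproducible stand-in for full Bayesian meta-regression tooling and
is documented as such; it shrinks raw stratum proportions toward the pooled
rate with a configurable prior strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

from .cohort import COMORBIDITIES, DomainError, ValidationError

__all__ = [
    "LifeTable",
    "DisabilityWeightMap",
    "PrevalenceEstimate",
    "BurdenResult",
    "yll",
    "combine_weights",
    "estimate_prevalence",
    "yld",
    "compute_dalys",
    "synthetic_life_table",
    "synthetic_disability_weights",
    "age_band",
]


# --------------------------------------------------------------------------
# Life table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Sex- and single-year-age-indexed residual life expectancy ``e_x``.

    ``table`` must contain columns ``sex`` ("male"/"female"), integer ``age``
    and ``ex`` (> 0, non-increasing in age beyond age 1 up to a small
    tolerance for table artifacts), covering at least ages 18–110.
    """

    table: pd.DataFrame
    _lookup: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"sex", "age", "ex"}
        if not required.issubset(t.columns):
            raise ValidationError(f"life table needs columns {sorted(required)}")
        if (t["ex"] <= 0).any():
            raise ValidationError("life expectancy e_x must be positive")
        lookup = {}
        for sex, sub in t.groupby("sex"):
            sub = sub.sort_values("age")
            ages = sub["age"].to_numpy()
            if set(range(18, 111)) - set(ages.tolist()):
                raise ValidationError(f"life table for {sex!r} must cover ages 18..110")
            ex = sub["ex"].to_numpy(dtype=float)
            beyond_1 = ages >= 1
            if (np.diff(ex[beyond_1]) > 1e-6).any():
                raise ValidationError(f"e_x for {sex!r} must be non-increasing beyond age 1")
            lookup[sex] = dict(zip(ages.tolist(), ex.tolist()))
        if set(lookup) != {"male", "female"}:
            raise ValidationError("life table must cover both sexes")
        object.__setattr__(self, "_lookup", lookup)

    def expectancy(self, sex: str, age: int) -> float:
        try:
            return self._lookup[sex][int(age)]
        except KeyError:
            ages = sorted(self._lookup.get(sex, {}))
            bound = f"[{ages[0]}, {ages[-1]}]" if ages else "(none)"
            raise DomainError(f"no life-table entry for sex={sex!r} age={age}; table domain {bound}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def synthetic_life_table(e0_male: float = 72.8, e0_female: float = 79.9) -> LifeTable:
    """A smooth synthetic complete life table with Gompertz–Makeham mortality.

    The Gompertz slope is fixed and the level is solved so that life
    expectancy at birth matches ``e0_male`` / ``e0_female`` (defaults shaped
    like Brazilian period expectancies).  Synthetic: a stand-in with the right
    structure for tests and examples, not any national table.
    """
    ages = np.arange(0, 121)

    def make_ex(e0: float) -> np.ndarray:
        b, makeham = 0.095, 6e-4

        def ex_at_birth(log_a: float) -> float:
            hazard = makeham + np.exp(log_a) * np.exp(b * ages)
            surv = np.exp(-np.concatenate([[0.0], np.cumsum(hazard[:-1])]))
            return float(surv[1:].sum() / surv[0] + 0.5)

        log_a = brentq(lambda la: ex_at_birth(la) - e0, -16, -4, xtol=1e-12)
        hazard = makeham + np.exp(log_a) * np.exp(b * ages)
        surv = np.exp(-np.concatenate([[0.0], np.cumsum(hazard[:-1])]))
        with np.errstate(invalid="ignore"):
            ex = np.array([surv[x + 1 :].sum() / surv[x] + 0.5 for x in ages])
        return ex

    rows = []
    for sex, e0 in (("male", e0_male), ("female", e0_female)):
        ex = make_ex(e0)
        for age, e in zip(ages.tolist(), ex.tolist()):
            if age <= 110:
                rows.append({"sex": sex, "age": age, "ex": round(e, 3)})
    return LifeTable(pd.DataFrame(rows))


def yll(age_at_death: float, sex: str, lt: LifeTable) -> float:
    """Years of life lost for one death: ``e_x`` at (sex, floor(age))."""
    return lt.expectancy(sex, int(np.floor(age_at_death)))


# --------------------------------------------------------------------------
# Disability weights
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DisabilityWeightMap:
    """mRS-level and comorbidity disability weights, each in [0, 1).

    mRS 0 (no symptoms) is pinned at weight 0.  A non-monotone mRS weight
    ladder is permitted but warned about, since severity should not decrease
    with worsening mRS.
    """

    mrs_weights: dict[int, float]
    comorbidity_weights: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.mrs_weights) != set(range(6)):
            raise ValidationError("mrs_weights must map levels 0..5")
        if self.mrs_weights[0] != 0.0:
            raise ValidationError("mRS 0 must have weight 0")
        for name, w in list(self.mrs_weights.items()) + list(self.comorbidity_weights.items()):
            if not 0.0 <= w < 1.0:
                raise ValidationError(f"weight for {name!r} must be in [0, 1), got {w}")
        ladder = [self.mrs_weights[k] for k in range(6)]
        if any(b < a for a, b in zip(ladder, ladder[1:])):
            warnings.warn("mRS weights are not non-decreasing in severity", stacklevel=2)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DisabilityWeightMap":
        """Read a ``kind,level,weight`` CSV (kind in {mrs, comorbidity})."""
        t = pd.read_csv(path, dtype={"level": str})
        if not {"kind", "level", "weight"}.issubset(t.columns):
            raise ValidationError("weights CSV needs columns kind,level,weight")
        mrs = {int(r.level): float(r.weight) for r in t[t["kind"] == "mrs"].itertuples()}
        com = {str(r.level): float(r.weight) for r in t[t["kind"] == "comorbidity"].itertuples()}
        return cls(mrs_weights=mrs, comorbidity_weights=com)

    def to_csv(self, path: str | Path) -> None:
        rows = [{"kind": "mrs", "level": k, "weight": w} for k, w in sorted(self.mrs_weights.items())]
        rows += [{"kind": "comorbidity", "level": k, "weight": w} for k, w in self.comorbidity_weights.items()]
        pd.DataFrame(rows).to_csv(path, index=False)


def synthetic_disability_weights() -> DisabilityWeightMap:
    """Synthetic default weights: an mRS ladder shaped like published
    stroke-severity disability weights plus modest chronic-condition weights.
    A documented stand-in for user-supplied weights, not an official set."""
    return DisabilityWeightMap(
        mrs_weights={0: 0.0, 1: 0.019, 2: 0.070, 3: 0.316, 4: 0.552, 5: 0.588},
        comorbidity_weights={
            "hypertension": 0.023, "cardiopathy": 0.072, "copd": 0.192,
            "renal": 0.104, "diabetes": 0.049, "extracranial_neoplasia": 0.288,
        },
    )


def combine_weights(weights: list[float], method: str = "complement") -> float:
    """Combine several disability weights into one health-state weight.

    ``"complement"`` (default) is the GBD multiplicative comorbidity
    correction ``1 - prod(1 - w_i)``: bounded in [0, 1), order-invariant,
    never exceeding the sum of the weights nor falling below their maximum.
    ``"product"`` returns the raw product of the weights (a sensitivity
    analysis; 0 for an empty list).
    """
    ws = list(weights)
    for w in ws:
        if not 0.0 <= w < 1.0:
            raise DomainError(f"disability weights must be in [0, 1), got {w}")
    if method == "complement":
        return float(1.0 - np.prod([1.0 - w for w in ws])) if ws else 0.0
    if method == "product":
        return float(np.prod(ws)) if ws else 0.0
    raise DomainError(f"unknown combination method {method!r}")


# --------------------------------------------------------------------------
# Prevalence (beta-binomial shrinkage stand-in)
# --------------------------------------------------------------------------

def age_band(age: np.ndarray | int, width: int = 5) -> np.ndarray | int:
    """Lower edge of the age band containing ``age`` (default 5-year bands)."""
    return (np.asarray(age) // width) * width if np.ndim(age) else (int(age) // width) * width


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Per (diagnosis, sex, age band) prevalent-case proportions with 95% intervals."""

    table: pd.DataFrame           # diagnosis_group, sex, band, k, n, estimate, ci_low, ci_high, empty
    band_width: int
    prior_strength: float

    def __post_init__(self) -> None:
        t = self.table
        if ((t["estimate"] < 0) | (t["estimate"] > 1)).any():
            raise ValidationError("prevalence estimates must be in [0, 1]")
        if ((t["ci_low"] > t["estimate"]) | (t["ci_high"] < t["estimate"])).any():
            raise ValidationError("intervals must contain the point estimate")

    def scaling(self, diagnosis: str, sex: str, band: int) -> float:
        t = self.table
        hit = t[(t["diagnosis_group"] == diagnosis) & (t["sex"] == sex) & (t["band"] == band)]
        if hit.empty:
            raise DomainError(f"no prevalence stratum for ({diagnosis}, {sex}, band {band})")
        return float(hit["estimate"].iloc[0])


def estimate_prevalence(
    frame: pd.DataFrame, band_width: int = 5, prior_strength: float = 10.0
) -> PrevalenceEstimate:
    """Beta-binomial shrinkage estimate of each diagnosis's share per sex x age band.

    Within each (sex, band) stratum the proportion of patients carrying each
    diagnosis is shrunk toward that diagnosis's pooled cohort share with a
    ``Beta(s * pooled, s * (1 - pooled))`` prior of strength ``s``
    (``prior_strength`` pseudo-patients).  The 95% interval is the central
    posterior interval.  Strata with no patients at all return the prior mean
    and are flagged ``empty``.
    """
    if frame.empty:
        raise DomainError("cohort is empty")
    if prior_strength <= 0:
        raise DomainError("prior_strength must be positive")
    work = frame[["diagnosis_group", "sex", "age"]].copy()
    work["band"] = age_band(work["age"].to_numpy(), band_width)
    pooled = work["diagnosis_group"].value_counts(normalize=True)
    bands = np.arange(work["band"].min(), work["band"].max() + band_width, band_width)
    rows = []
    sizes = work.groupby(["sex", "band"]).size()
    counts = work.groupby(["sex", "band", "diagnosis_group"]).size()
    for diagnosis in pooled.index:
        p0 = float(pooled[diagnosis])
        a0, b0 = prior_strength * p0, prior_strength * (1 - p0)
        for sex in ("male", "female"):
            for band in bands.tolist():
                n = int(sizes.get((sex, band), 0))
                k = int(counts.get((sex, band, diagnosis), 0))
                a, b = k + a0, n - k + b0
                rows.append(
                    {
                        "diagnosis_group": diagnosis, "sex": sex, "band": band,
                        "k": k, "n": n,
                        "estimate": a / (a + b),
                        "ci_low": float(beta_dist.ppf(0.025, a, b)),
                        "ci_high": float(beta_dist.ppf(0.975, a, b)),
                        "empty": n == 0,
                    }
                )
    return PrevalenceEstimate(
        table=pd.DataFrame(rows), band_width=band_width, prior_strength=prior_strength
    )


# --------------------------------------------------------------------------
# YLD / DALY
# --------------------------------------------------------------------------

def _patient_weights(frame: pd.DataFrame, dw: DisabilityWeightMap, method: str) -> np.ndarray:
    out = np.zeros(len(frame))
    mrs = frame["mrs"].to_numpy(dtype=float)
    for i, (_, row) in enumerate(frame.iterrows()):
        ws = [dw.mrs_weights[int(mrs[i])]]
        ws += [dw.comorbidity_weights.get(c, 0.0) for c in COMORBIDITIES if row[c]]
        out[i] = combine_weights(ws, method=method)
    return out


def yld(
    frame: pd.DataFrame,
    dw: DisabilityWeightMap,
    prev: PrevalenceEstimate | None = None,
    horizon_years: float = 1.0,
    method: str = "complement",
) -> tuple[float, pd.Series, int]:
    """Years lived with disability for the survivors of a cohort frame.

    Per surviving patient: comorbidity-corrected disability weight x
    ``horizon_years`` x the patient's stratum prevalence scaling (1 when
    ``prev`` is None).  Deaths contribute 0; survivors with missing mRS are
    excluded and counted, never imputed.  Returns
    ``(total, per-patient contributions indexed like frame, n_excluded)``.
    """
    if horizon_years <= 0:
        raise DomainError("horizon_years must be positive")
    contrib = pd.Series(0.0, index=frame.index)
    survivors = ~frame["died"].to_numpy(dtype=bool)
    has_mrs = frame["mrs"].notna().to_numpy()
    usable = survivors & has_mrs
    n_excluded = int((survivors & ~has_mrs).sum())
    if usable.any():
        sub = frame.loc[usable]
        w = _patient_weights(sub, dw, method)
        if prev is not None:
            scale = np.array(
                [
                    prev.scaling(r.diagnosis_group, r.sex, int(age_band(r.age, prev.band_width)))
                    for r in sub.itertuples()
                ]
            )
        else:
            scale = 1.0
        contrib.loc[usable] = w * horizon_years * scale
    return float(contrib.sum()), contrib, n_excluded


@dataclass
class BurdenResult:
    """Cohort burden totals plus stratified breakdowns.

    ``ledger`` holds per-patient YLL/YLD/DALY; ``by_*`` tables are groupby
    sums of the same ledger, so every stratification reconciles with the
    totals exactly (up to float associativity).
    """

    yll_total: float
    yld_total: float
    daly_total: float
    ledger: pd.DataFrame
    by_diagnosis: pd.DataFrame
    by_sex: pd.DataFrame
    by_age_band: pd.DataFrame
    by_hs_category: pd.DataFrame
    n_survivors_missing_mrs: int = 0

    def strata(self) -> dict[str, pd.DataFrame]:
        return {
            "diagnosis_group": self.by_diagnosis,
            "sex": self.by_sex,
            "age_band": self.by_age_band,
            "hs_category": self.by_hs_category,
        }


def compute_dalys(
    frame: pd.DataFrame,
    lt: LifeTable,
    dw: DisabilityWeightMap,
    prev: PrevalenceEstimate | None = None,
    horizon_years: float = 1.0,
    method: str = "complement",
) -> BurdenResult:
    """Full DALY accounting for a cohort frame.

    Deaths contribute ``e_x``-based YLL; survivors contribute weighted YLD
    (see :func:`yld`).  Returns totals and stratifications by diagnosis
    group, sex, 5-year age band and Hs category, all derived from one
    per-patient ledger so that DALY = YLL + YLD holds exactly row by row.
    """
    band_width = prev.band_width if prev is not None else 5
    if frame.empty:
        empty = pd.DataFrame(columns=["yll", "yld", "daly"])
        return BurdenResult(0.0, 0.0, 0.0, empty, empty, empty, empty, empty)
    died = frame["died"].to_numpy(dtype=bool)
    yll_col = np.zeros(len(frame))
    for pos in np.nonzero(died)[0]:
        row = frame.iloc[pos]
        yll_col[pos] = yll(row["age"], row["sex"], lt)
    yld_total, yld_col, n_excluded = yld(frame, dw, prev=prev, horizon_years=horizon_years, method=method)

    ledger = pd.DataFrame(
        {
            "patient_id": frame["patient_id"].to_numpy(),
            "diagnosis_group": frame["diagnosis_group"].to_numpy(),
            "sex": frame["sex"].to_numpy(),
            "age_band": age_band(frame["age"].to_numpy(), band_width),
            "hs_category": frame["hs_category"].to_numpy(),
            "yll": yll_col,
            "yld": yld_col.to_numpy(),
        }
    )
    ledger["daly"] = ledger["yll"] + ledger["yld"]

    def by(key: str) -> pd.DataFrame:
        return ledger.groupby(key)[["yll", "yld", "daly"]].sum()

    yll_total = float(ledger["yll"].sum())
    return BurdenResult(
        yll_total=yll_total,
        yld_total=yld_total,
        daly_total=yll_total + yld_total,
        ledger=ledger,
        by_diagnosis=by("diagnosis_group"),
        by_sex=by("sex"),
        by_age_band=by("age_band"),
        by_hs_category=by("hs_category"),
        n_survivors_missing_mrs=n_excluded,
    )
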