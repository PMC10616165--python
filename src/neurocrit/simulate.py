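"""Synthetic neurocritical-care cohort generator.

Emulates the statistical structure of a multicentre Brazilian neuro-ICU
cohort: a ten-group diagnosis mix, group-wise age/sex/severity-score
distributions, a per-group secondary-injury (Hs) burden with physiology
drawn to be *exactly consistent* with the generated Hs flags, comorbidity
prevalences, and a configurable logistic outcome model linking age, sex,
GCS, Hs category, insurance and admission type to ICU death, with survivor
mRS allocated by an ordinal-logistic rule on the same linear predictor.

Reproducibility contract: every variable draws from its own counter-based
Philox stream keyed by ``(seed, variable name)`` and consumes exactly one
value per patient, so cohorts are deterministic given the seed and extending
``n_patients`` never perturbs earlier patients' draws.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort import (
    COMORBIDITIES,
    DIAGNOSIS_GROUPS,
    HS_FLAGS,
    PatientRecord,
    PhysiologySnapshot,
)

__all__ = [
    "GroupParams",
    "OutcomeModel",
    "CohortSpec",
    "ConfigurationError",
    "generate_frame",
    "generate_cohort",
    "true_params",
    "recoverability_report",
]


class ConfigurationError(ValueError):
    """A cohort specification is internally inconsistent or degenerate."""


# --------------------------------------------------------------------------
# Specification types and their defaults
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Per-diagnosis-group marginals.

    Quantile triples ``(q1, median, q3)`` parameterize a piecewise-linear
    quantile function (a declared convention for skewed ICU scores, not an
    inference about any real dataset); Hs category probabilities are the
    within-group mix of 0 / 1 / 2 / >=3 secondary injuries.
    """

    weight: float                      # share of the diagnosis mix
    age_mean: float
    age_sd: float
    male_prop: float
    gcs_q: tuple[float, float, float]
    apache2_q: tuple[float, float, float]
    saps3_q: tuple[float, float, float]
    sofa_q: tuple[float, float, float]
    los_q: tuple[float, float, float]
    hs_category_probs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be > 0")
        if not 0 <= self.male_prop <= 1:
            raise ConfigurationError("male_prop must be in [0, 1]")
        if any(p < 0 for p in self.hs_category_probs):
            raise ConfigurationError("hs_category_probs must be non-negative")
        if abs(sum(self.hs_category_probs) - 1.0) > 1e-9:
            raise ConfigurationError("hs_category_probs must sum to 1")
        for q in (self.gcs_q, self.apache2_q, self.saps3_q, self.sofa_q, self.los_q):
            if not (q[0] <= q[1] <= q[2]):
                raise ConfigurationError(f"quantile triple {q} must be non-decreasing")


def _default_groups() -> dict[str, GroupParams]:
    raw = {
        # group: (n, age_mean, age_sd, male, gcs_q, apache2_q, saps3_q, sofa_q, los_q, hs_counts)
        "NPO": (317, 53.4, 14.7, 0.413, (14, 15, 15), (4, 7, 10), (24, 31, 39), (0, 1, 3), (2, 3, 5), (162, 96, 41, 18)),
        "TBI": (218, 54.3, 22.1, 0.743, (3, 9, 14), (10, 14, 21), (38, 47, 57), (2, 5, 8), (4, 11, 29), (64, 51, 49, 54)),
        "IS": (211, 69.3, 16.9, 0.507, (12, 14, 15), (7, 11, 16), (42, 52, 58), (0, 2, 4), (3, 4, 11), (109, 55, 30, 17)),
        "ENC": (155, 65.7, 20.2, 0.465, (9, 13, 14), (10, 15, 25), (47, 57, 68), (2, 4, 8), (3, 6, 17.5), (47, 39, 32, 37)),
        "seizures": (91, 58.7, 22.7, 0.505, (11, 14, 15), (6, 10, 15), (33, 41, 54), (0, 2, 4), (2, 4, 9), (44, 24, 14, 9)),
        "ICH": (77, 62.0, 15.3, 0.481, (4, 10, 14), (9, 15, 19), (44, 54.5, 65.5), (2, 4, 7), (6, 16, 30), (30, 20, 13, 14)),
        "SAH": (70, 57.6, 14.2, 0.314, (3, 10, 14), (8, 14, 20), (40, 48, 60), (2, 4, 8), (4, 11.5, 22), (24, 20, 14, 12)),
        "SNI": (25, 55.7, 17.6, 0.760, (4, 10, 14), (12, 20, 24), (44.5, 59, 65.5), (1.5, 6, 9), (4, 13, 26), (6, 5, 4, 10)),
        "SCI": (19, 36.5, 18.5, 0.737, (15, 15, 15), (3, 7, 12), (27, 35, 43), (1, 3, 4), (7.5, 30, 30), (8, 5, 5, 1)),
        "NMD": (11, 50.0, 20.8, 0.727, (14, 15, 15), (5, 7, 10), (36, 42, 49), (0, 0, 2), (3, 4, 30), (6, 3, 1, 1)),
    }
    total = sum(v[0] for v in raw.values())
    groups = {}
    for g, (n, am, asd, male, gcs, ap, sp, so, los, hs) in raw.items():
        hs_total = sum(hs)
        groups[g] = GroupParams(
            weight=n / total,
            age_mean=am,
            age_sd=asd,
            male_prop=male,
            gcs_q=gcs,
            apache2_q=ap,
            saps3_q=sp,
            sofa_q=so,
            los_q=los,
            hs_category_probs=tuple(c / hs_total for c in hs),
        )
    return groups


# Default outcome log-odds: per-year age, male sex, per-point GCS, Hs category
# vs zero, public vs private insurance, emergency vs elective admission.
_DEATH_ORS = {
    "age": 1.022, "male": 1.222, "gcs": 0.895,
    "hs_one": 1.978, "hs_two": 3.86, "hs_three_plus": 8.663,
    "public": 2.353, "emergency": 5.77,
}
_SEVERITY_ORS = {
    "age": 1.021, "male": 1.03, "gcs": 0.835,
    "hs_one": 1.259, "hs_two": 2.848, "hs_three_plus": 4.761,
    "public": 2.784, "emergency": 4.359,
}

# Calibrated against the generator's own covariate distribution so that the
# default spec yields ~15.7% ICU mortality and survivor mRS margins close to
# the reference cohort's 283/201/121/100/154/140 split (see docs/methods.md).
_DEATH_INTERCEPT = -4.7166
_MRS_CUTPOINTS = (-0.2746, 0.8349, 1.473, 2.0478, 3.2185)

COVARIATE_ORDER = ("age", "male", "gcs", "hs_one", "hs_two", "hs_three_plus", "public", "emergency")


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic death model and ordinal survivor-mRS allocation rule.

    ``death_coefs`` / ``severity_coefs`` are log-odds on the model-1 covariate
    set.  Survivors get ``P(mRS <= k) = expit(cutpoints[k] - severity LP)``;
    deaths are mRS 6 by construction.  ``death_intercept`` may be ``-inf`` to
    force a death-free cohort.
    """

    death_intercept: float = _DEATH_INTERCEPT
    death_coefs: dict[str, float] = field(
        default_factory=lambda: {k: float(np.log(v)) for k, v in _DEATH_ORS.items()}
    )
    severity_coefs: dict[str, float] = field(
        default_factory=lambda: {k: float(np.log(v)) for k, v in _SEVERITY_ORS.items()}
    )
    survivor_mrs_cutpoints: tuple[float, ...] = _MRS_CUTPOINTS

    def __post_init__(self) -> None:
        for name, coefs in (("death_coefs", self.death_coefs), ("severity_coefs", self.severity_coefs)):
            missing = set(COVARIATE_ORDER) - set(coefs)
            if missing:
                raise ConfigurationError(f"{name} missing terms {sorted(missing)}")
            if not all(np.isfinite(v) for v in coefs.values()):
                raise ConfigurationError(f"{name} must be finite")
        if np.isnan(self.death_intercept) or self.death_intercept == np.inf:
            raise ConfigurationError("death_intercept must be finite or -inf")
        cp = self.survivor_mrs_cutpoints
        if len(cp) != 6 - 1 or any(b <= a for a, b in zip(cp, cp[1:])):
            raise ConfigurationError("survivor_mrs_cutpoints must be 5 strictly increasing values")

    @classmethod
    def null(cls, death_rate: float = 0.157) -> "OutcomeModel":
        """All covariate effects zero; marginal death probability = ``death_rate``."""
        zeros = {k: 0.0 for k in COVARIATE_ORDER}
        return cls(
            death_intercept=float(np.log(death_rate / (1 - death_rate))),
            death_coefs=zeros,
            severity_coefs=dict(zeros),
        )


# Marginal Hs flag prevalences used as sampling weights when choosing *which*
# flags make up a patient's Hs count (weighted sampling without replacement).
_HS_FLAG_WEIGHTS = {
    "hypotension": 0.224, "hypoxemia": 0.060, "hyperthermia": 0.106,
    "hypercapnia": 0.096, "hypocapnia": 0.193, "hypoglycaemia": 0.027,
    "hyponatremia": 0.168, "hypothermia": 0.101,
    "intracranial_hypertension": 0.075, "herniation": 0.064,
}


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic cohort deterministically."""

    n_patients: int = 1194
    seed: int = 0
    groups: dict[str, GroupParams] = field(default_factory=_default_groups)
    comorbidity_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.505, "cardiopathy": 0.148, "copd": 0.043,
            "renal": 0.070, "diabetes": 0.183, "extracranial_neoplasia": 0.075,
        }
    )
    insurance_public_prob: float = 0.495
    emergency_prob: float = 0.734
    location_probs: tuple[float, float, float, float] = (0.475, 0.358, 0.068, 0.099)
    hs_flag_weights: dict[str, float] = field(default_factory=lambda: dict(_HS_FLAG_WEIGHTS))
    # probabilities of a missing score / missing survivor mRS
    missing_saps3: float = 35 / 1194
    missing_sofa: float = 54 / 1194
    missing_mrs: float = 7 / 1006
    survivor_disposition: tuple[float, float, float] = (832 / 1006, 22 / 1006, 152 / 1006)
    extra_hs_count_probs: tuple[float, ...] = (0.60, 0.25, 0.10, 0.05)  # counts 3..6 within "three or more"
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if set(self.groups) != set(DIAGNOSIS_GROUPS):
            raise ConfigurationError("groups must cover exactly the ten diagnosis groups")
        if abs(sum(g.weight for g in self.groups.values()) - 1.0) > 1e-9:
            raise ConfigurationError("diagnosis mix must sum to 1")
        if any(g.weight < 0 for g in self.groups.values()):
            raise ConfigurationError("diagnosis mix must be non-negative")
        for name, p in (("insurance_public_prob", self.insurance_public_prob),
                        ("emergency_prob", self.emergency_prob),
                        ("missing_saps3", self.missing_saps3),
                        ("missing_sofa", self.missing_sofa),
                        ("missing_mrs", self.missing_mrs)):
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for probs, name in ((self.location_probs, "location_probs"),
                            (self.survivor_disposition, "survivor_disposition"),
                            (self.extra_hs_count_probs, "extra_hs_count_probs")):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must be a probability vector summing to 1")
        if set(self.comorbidity_prevalence) != set(COMORBIDITIES):
            raise ConfigurationError("comorbidity_prevalence must cover the six comorbidities")
        if set(self.hs_flag_weights) != set(HS_FLAGS):
            raise ConfigurationError("hs_flag_weights must cover the ten Hs flags")
        if any(w <= 0 for w in self.hs_flag_weights.values()):
            raise ConfigurationError("hs_flag_weights must be positive")

    def diagnosis_mix(self) -> np.ndarray:
        return np.array([self.groups[g].weight for g in DIAGNOSIS_GROUPS])


# --------------------------------------------------------------------------
# RNG plumbing: one Philox stream per variable, one draw per patient
# --------------------------------------------------------------------------

def _stream(seed: int, name: str) -> np.random.Generator:
    key = zlib.crc32(name.encode("ascii"))
    return np.random.Generator(np.random.Philox(np.random.SeedSequence([int(seed), key])))


def _uniform(seed: int, name: str, n: int) -> np.ndarray:
    return _stream(seed, name).random(n)


def _gumbel(seed: int, name: str, n: int) -> np.ndarray:
    u = _stream(seed, name).random(n)
    return -np.log(-np.log(np.clip(u, 1e-300, 1 - 1e-16)))


def _interp_quantile(u: np.ndarray, q: tuple[float, float, float], lo: float, hi: float) -> np.ndarray:
    """Piecewise-linear quantile function through (q1, median, q3) with Tukey-fence tails."""
    q1, med, q3 = q
    iqr = q3 - q1
    lo = max(lo, min(q1, q1 - 1.5 * iqr))
    hi = min(hi, max(q3, q3 + 1.5 * iqr))
    nodes_p = [0.0, 0.25, 0.5, 0.75, 1.0]
    nodes_v = [min(lo, q1), q1, med, q3, max(hi, q3)]
    return np.interp(u, nodes_p, nodes_v)


def _per_group(
    seed: int, name: str, n: int, group_idx: np.ndarray, fn
) -> np.ndarray:
    """Apply a per-group transform to one uniform stream."""
    u = _uniform(seed, name, n)
    out = np.empty(n)
    for gi, g in enumerate(DIAGNOSIS_GROUPS):
        mask = group_idx == gi
        if mask.any():
            out[mask] = fn(u[mask], g)
    return out


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

# Sampling intervals for physiology given flag status: (normal, abnormal).
_PHYS_RANGES = {
    "map_mmHg": ((65.0, 110.0), (40.0, 65.0)),       # hypotension
    "sbp_mmHg": ((90.0, 160.0), (60.0, 90.0)),       # hypotension
    "pao2_mmHg": ((60.0, 150.0), (40.0, 60.0)),      # hypoxemia
    "sao2_pct": ((90.0, 100.0), (75.0, 90.0)),       # hypoxemia
    "spo2_pct": ((90.0, 100.0), (75.0, 90.0)),       # hypoxemia
    "glucose_mg_dL": ((60.0, 200.0), (30.0, 60.0)),  # hypoglycaemia
    "sodium_mmol_L": ((135.0, 150.0), (120.0, 135.0)),  # hyponatremia
    "icp_mmHg": ((2.0, 25.0), (26.0, 60.0)),         # intracranial hypertension
}


def _select_flags(spec: CohortSpec, counts: np.ndarray) -> np.ndarray:
    """Weighted sampling without replacement of each patient's Hs flag set.

    Gumbel-top-k on log-weights; hyperthermia and hypothermia are mutually
    exclusive (a single body temperature cannot satisfy both rules), so the
    lower-scored of the two is skipped and the next candidate taken instead.
    """
    n = len(counts)
    scores = np.empty((n, len(HS_FLAGS)))
    for fi, flag in enumerate(HS_FLAGS):
        scores[:, fi] = np.log(spec.hs_flag_weights[flag]) + _gumbel(spec.seed, f"hsflag_{flag}", n)
    order = np.argsort(-scores, axis=1)
    hyper = HS_FLAGS.index("hyperthermia")
    hypo = HS_FLAGS.index("hypothermia")
    flags = np.zeros((n, len(HS_FLAGS)), dtype=bool)
    for i in np.nonzero(counts > 0)[0]:
        c = counts[i]
        chosen: list[int] = []
        for fi in order[i]:
            if fi == hyper and hypo in chosen:
                continue
            if fi == hypo and hyper in chosen:
                continue
            chosen.append(fi)
            if len(chosen) == c:
                break
        flags[i, chosen] = True
    return flags


def _linear_predictor(coefs: dict[str, float], cols: dict[str, np.ndarray]) -> np.ndarray:
    lp = np.zeros(len(cols["age"]))
    for term in COVARIATE_ORDER:
        lp += coefs[term] * cols[term]
    return lp


def _generate_columns(spec: CohortSpec) -> dict[str, np.ndarray]:
    n = spec.n_patients
    seed = spec.seed
    mix = spec.diagnosis_mix()
    group_idx = np.searchsorted(np.cumsum(mix), _uniform(seed, "diagnosis", n), side="right")
    group_idx = np.minimum(group_idx, len(DIAGNOSIS_GROUPS) - 1)

    def age_fn(u, g):
        gp = spec.groups[g]
        a, b = (18.0 - gp.age_mean) / gp.age_sd, (110.0 - gp.age_mean) / gp.age_sd
        return truncnorm.ppf(u, a, b, loc=gp.age_mean, scale=gp.age_sd)

    age = np.floor(_per_group(seed, "age", n, group_idx, age_fn)).astype(int)
    age = np.clip(age, 18, 109)

    male = _uniform(seed, "sex", n) < np.array([spec.groups[g].male_prop for g in DIAGNOSIS_GROUPS])[group_idx]

    def score_fn(attr, lo, hi):
        def fn(u, g):
            return _interp_quantile(u, getattr(spec.groups[g], attr), lo, hi)
        return fn

    gcs = np.rint(_per_group(seed, "gcs", n, group_idx, score_fn("gcs_q", 3, 15))).astype(int)
    gcs = np.clip(gcs, 3, 15)
    apache2 = np.clip(np.rint(_per_group(seed, "apache2", n, group_idx, score_fn("apache2_q", 0, 71))), 0, 71).astype(int)
    saps3 = np.clip(np.rint(_per_group(seed, "saps3", n, group_idx, score_fn("saps3_q", 0, 130))), 0, 130).astype(int)
    sofa = np.clip(np.rint(_per_group(seed, "sofa", n, group_idx, score_fn("sofa_q", 0, 24))), 0, 24).astype(int)
    los = np.clip(np.rint(_per_group(seed, "los", n, group_idx, score_fn("los_q", 0, 30))), 0, 30).astype(int)

    cat_probs = np.array([spec.groups[g].hs_category_probs for g in DIAGNOSIS_GROUPS])
    u_cat = _uniform(seed, "hs_category", n)
    cat = (u_cat[:, None] >= np.cumsum(cat_probs, axis=1)[group_idx]).sum(axis=1)
    extra = np.searchsorted(np.cumsum(spec.extra_hs_count_probs), _uniform(seed, "hs_extra", n), side="right")
    extra = np.minimum(extra, len(spec.extra_hs_count_probs) - 1)
    counts = np.where(cat == 3, 3 + extra, cat)

    flags = _select_flags(spec, counts)
    flag_of = {f: flags[:, i] for i, f in enumerate(HS_FLAGS)}

    phys: dict[str, np.ndarray] = {}
    flag_for_field = {
        "map_mmHg": "hypotension", "sbp_mmHg": "hypotension",
        "pao2_mmHg": "hypoxemia", "sao2_pct": "hypoxemia", "spo2_pct": "hypoxemia",
        "glucose_mg_dL": "hypoglycaemia", "sodium_mmol_L": "hyponatremia",
        "icp_mmHg": "intracranial_hypertension",
    }
    for fld, ((nlo, nhi), (alo, ahi)) in _PHYS_RANGES.items():
        u = _uniform(seed, f"phys_{fld}", n)
        abnormal = flag_of[flag_for_field[fld]]
        phys[fld] = np.where(abnormal, alo + u * (ahi - alo), nlo + u * (nhi - nlo))

    # temperature: three-way (hypothermia < 35, normal [35, 37.5], hyperthermia > 37.5)
    u_t = _uniform(seed, "phys_temp_C", n)
    temp = 35.0 + u_t * 2.5
    temp = np.where(flag_of["hyperthermia"], 37.6 + u_t * (41.0 - 37.6), temp)
    temp = np.where(flag_of["hypothermia"], 30.0 + u_t * (35.0 - 30.0), temp)
    phys["temp_C"] = temp

    # CO2 / respiratory rate: hypercapnia is PaCO2 > 45 or RR < 8; hypocapnia PaCO2 < 35.
    # When both are present, hypocapnia fires through PaCO2 and hypercapnia through RR.
    u_c = _uniform(seed, "phys_paco2_mmHg", n)
    u_r = _uniform(seed, "phys_rr_ipm", n)
    hyper_c, hypo_c = flag_of["hypercapnia"], flag_of["hypocapnia"]
    paco2 = 35.0 + u_c * 10.0
    paco2 = np.where(hyper_c & ~hypo_c, 46.0 + u_c * (70.0 - 46.0), paco2)
    paco2 = np.where(hypo_c, 25.0 + u_c * (35.0 - 25.0), paco2)
    rr = 10.0 + u_r * 18.0
    rr = np.where(hyper_c & hypo_c, 4.0 + u_r * (8.0 - 4.0), rr)
    phys["paco2_mmHg"] = paco2
    phys["rr_ipm"] = rr

    comorb = {
        c: _uniform(seed, f"comorb_{c}", n) < spec.comorbidity_prevalence[c]
        for c in COMORBIDITIES
    }
    public = _uniform(seed, "insurance", n) < spec.insurance_public_prob
    emergency = _uniform(seed, "admission", n) < spec.emergency_prob
    loc_idx = np.searchsorted(np.cumsum(spec.location_probs), _uniform(seed, "location", n), side="right")
    loc_idx = np.minimum(loc_idx, 3)

    hs_category = np.array(["zero", "one", "two", "three_plus"])[np.minimum(counts, 3)]
    model_cols = {
        "age": age.astype(float),
        "male": male.astype(float),
        "gcs": gcs.astype(float),
        "hs_one": (counts == 1).astype(float),
        "hs_two": (counts == 2).astype(float),
        "hs_three_plus": (counts >= 3).astype(float),
        "public": public.astype(float),
        "emergency": emergency.astype(float),
    }
    om = spec.outcome_model
    p_death = expit(om.death_intercept + _linear_predictor(om.death_coefs, model_cols))
    died = _uniform(seed, "death", n) < p_death

    eta = _linear_predictor(om.severity_coefs, model_cols)
    cum = expit(np.array(om.survivor_mrs_cutpoints)[None, :] - eta[:, None])
    mrs = (_uniform(seed, "mrs", n)[:, None] > cum).sum(axis=1)  # survivor mRS 0..5
    mrs = np.where(died, 6, mrs)

    disp = np.searchsorted(np.cumsum(spec.survivor_disposition), _uniform(seed, "disposition", n), side="right")
    disp = np.minimum(disp, 2)
    outcome_status = np.where(
        died, "death", np.array(["icu_discharge", "transfer", "continued_hospitalization"])[disp]
    )

    miss_saps3 = _uniform(seed, "miss_saps3", n) < spec.missing_saps3
    miss_sofa = _uniform(seed, "miss_sofa", n) < spec.missing_sofa
    miss_mrs = (~died) & (_uniform(seed, "miss_mrs", n) < spec.missing_mrs)

    return {
        "group_idx": group_idx,
        "age": age, "male": male, "gcs": gcs, "apache2": apache2,
        "saps3": saps3, "sofa": sofa, "los_days": los,
        "hs_counts": counts, "hs_category": hs_category, "flags": flags,
        **{f"phys_{k}": v for k, v in phys.items()},
        **{f"comorb_{c}": v for c, v in comorb.items()},
        "public": public, "emergency": emergency, "loc_idx": loc_idx,
        "died": died, "mrs": mrs, "outcome_status": outcome_status,
        "miss_saps3": miss_saps3, "miss_sofa": miss_sofa, "miss_mrs": miss_mrs,
    }


_LOCATIONS = ("emergency_department", "operating_room", "ward", "other")


def generate_frame(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort as an analysis DataFrame (no per-record validation).

    Column layout matches :func:`neurocrit.io.cohort_to_frame`, so the frame
    feeds the model suite and burden engine directly.  ``saps3``/``sofa``/``mrs``
    carry the configured missingness as pandas NA.
    """
    c = _generate_columns(spec)
    n = spec.n_patients
    frame = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:06d}" for i in range(n)],
            "age": c["age"],
            "sex": np.where(c["male"], "male", "female"),
            "male": c["male"],
            "diagnosis_group": np.array(DIAGNOSIS_GROUPS)[c["group_idx"]],
            "insurance": np.where(c["public"], "public", "private"),
            "public": c["public"],
            "admission_type": np.where(c["emergency"], "emergency", "elective"),
            "emergency": c["emergency"],
            "location_before_icu": np.array(_LOCATIONS)[c["loc_idx"]],
            "gcs": c["gcs"],
            "apache2": c["apache2"],
            "saps3": pd.array(np.where(c["miss_saps3"], -1, c["saps3"]), dtype="Int64"),
            "sofa": pd.array(np.where(c["miss_sofa"], -1, c["sofa"]), dtype="Int64"),
            **{cm: c[f"comorb_{cm}"] for cm in COMORBIDITIES},
            "hs_count": c["hs_counts"],
            "hs_category": c["hs_category"],
            "outcome_status": c["outcome_status"],
            "died": c["died"],
            "mrs": pd.array(np.where(c["miss_mrs"], -1, c["mrs"]), dtype="Int64"),
            "los_days": c["los_days"],
        }
    )
    frame.loc[frame["saps3"] < 0, "saps3"] = pd.NA
    frame.loc[frame["sofa"] < 0, "sofa"] = pd.NA
    frame.loc[frame["mrs"] < 0, "mrs"] = pd.NA
    frame["unfavourable"] = (frame["mrs"] >= 4).astype("boolean")
    frame.loc[frame["mrs"].isna(), "unfavourable"] = pd.NA
    return frame


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate a cohort as validated records, physiology included.

    Physiology is drawn inside flag-consistent intervals, so
    :func:`neurocrit.cohort.classify_hs` reproduces each patient's generated
    Hs set exactly (this is re-checked by record validation on construction).
    """
    c = _generate_columns(spec)
    records = []
    for i in range(spec.n_patients):
        flags = frozenset(f for fi, f in enumerate(HS_FLAGS) if c["flags"][i, fi])
        phys = PhysiologySnapshot(
            map_mmHg=float(c["phys_map_mmHg"][i]),
            sbp_mmHg=float(c["phys_sbp_mmHg"][i]),
            pao2_mmHg=float(c["phys_pao2_mmHg"][i]),
            sao2_pct=float(c["phys_sao2_pct"][i]),
            spo2_pct=float(c["phys_spo2_pct"][i]),
            temp_C=float(c["phys_temp_C"][i]),
            paco2_mmHg=float(c["phys_paco2_mmHg"][i]),
            rr_ipm=float(c["phys_rr_ipm"][i]),
            glucose_mg_dL=float(c["phys_glucose_mg_dL"][i]),
            sodium_mmol_L=float(c["phys_sodium_mmol_L"][i]),
            icp_mmHg=float(c["phys_icp_mmHg"][i]),
            herniation_clinical="herniation" in flags,
        )
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:06d}",
                age=int(c["age"][i]),
                sex="male" if c["male"][i] else "female",
                diagnosis_group=DIAGNOSIS_GROUPS[c["group_idx"][i]],
                insurance="public" if c["public"][i] else "private",
                admission_type="emergency" if c["emergency"][i] else "elective",
                location_before_icu=_LOCATIONS[c["loc_idx"][i]],
                gcs=int(c["gcs"][i]),
                apache2=int(c["apache2"][i]),
                saps3=None if c["miss_saps3"][i] else int(c["saps3"][i]),
                sofa=None if c["miss_sofa"][i] else int(c["sofa"][i]),
                comorbidities=frozenset(cm for cm in COMORBIDITIES if c[f"comorb_{cm}"][i]),
                physiology=phys,
                hs_flags=flags,
                outcome_status=str(c["outcome_status"][i]),
                mrs=None if c["miss_mrs"][i] else int(c["mrs"][i]),
                los_days=int(c["los_days"][i]),
            )
        )
    return records


def true_params(spec: CohortSpec) -> dict:
    """The generating parameters as a JSON-serializable dict (sidecar for recovery tests)."""
    om = spec.outcome_model
    return {
        "n_patients": spec.n_patients,
        "seed": spec.seed,
        "diagnosis_mix": {g: spec.groups[g].weight for g in DIAGNOSIS_GROUPS},
        "death_intercept": om.death_intercept,
        "death_log_odds": dict(om.death_coefs),
        "death_odds_ratios": {k: float(np.exp(v)) for k, v in om.death_coefs.items()},
        "severity_log_odds": dict(om.severity_coefs),
        "survivor_mrs_cutpoints": list(om.survivor_mrs_cutpoints),
        "comorbidity_prevalence": dict(spec.comorbidity_prevalence),
        "insurance_public_prob": spec.insurance_public_prob,
        "emergency_prob": spec.emergency_prob,
    }


def recoverability_report(spec: CohortSpec, n: int | None = None, seed: int | None = None) -> pd.DataFrame:
    """Generate a cohort and check that the mortality model recovers the configured ORs.

    Fits the model-1 specification (age, sex, GCS, Hs category, insurance,
    admission) for ICU mortality on a fresh cohort and tabulates configured vs
    estimated log-odds with Wald 95% CIs and a coverage flag.  Perfect
    separation is reported in the table, never silently dropped.
    """
    from .models import MODEL_SPECS, run_model
    from .stats import SeparationError

    if n is not None or seed is not None:
        spec = dataclasses.replace(
            spec,
            n_patients=n if n is not None else spec.n_patients,
            seed=seed if seed is not None else spec.seed,
        )
    frame = generate_frame(spec)
    spec1 = next(s for s in MODEL_SPECS if s.name == "model1_gcs_hs" and s.outcome == "mortality")
    truth = spec.outcome_model.death_coefs
    try:
        fit = run_model(frame, spec1)
    except SeparationError as exc:
        return pd.DataFrame(
            {
                "term": list(COVARIATE_ORDER),
                "true_coef": [truth[t] for t in COVARIATE_ORDER],
                "estimate": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "covered": False,
                "separation": True,
                "note": str(exc),
            }
        ).set_index("term")
    rows = []
    for term in COVARIATE_ORDER:
        est = fit.table.loc[term]
        rows.append(
            {
                "term": term,
                "true_coef": truth[term],
                "true_or": float(np.exp(truth[term])),
                "estimate": float(est["coef"]),
                "or_": float(est["or_"]),
                "ci_low": float(est["ci_low"]),
                "ci_high": float(est["ci_high"]),
                "covered": bool(est["ci_low"] <= np.exp(truth[term]) <= est["ci_high"]),
                "separation": False,
            }
        )
    report = pd.DataFrame(rows).set_index("term")
    report.attrs["n_used"] = fit.n_used
    report.attrs["converged"] = fit.converged
    return report
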