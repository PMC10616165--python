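"""The four prognostic model specifications and the suite runner.

Each specification is a logistic model for one of the two study outcomes
(ICU mortality; unfavourable 30-day functional outcome, mRS 4-6):

* ``model1_gcs_hs`` — age, male sex, GCS, Hs category (one/two/three_plus vs
  zero), public insurance, emergency admission;
* ``model2_apache`` — male sex, APACHE II, public insurance, emergency;
* ``model3_saps3``  — male sex, SAPS III, public insurance, emergency;
* ``model4_sofa``   — age, male sex, SOFA, public insurance, emergency.

Models are fitted on complete cases only: rows missing any covariate or the
outcome are dropped and counted, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import FitResult, auc, fit_logistic

__all__ = ["ModelSpec", "MODEL_SPECS", "ConfigurationError", "build_design", "run_model", "run_model_suite", "tidy_results"]


class ConfigurationError(ValueError):
    """A model references a column the cohort does not provide."""


@dataclass(frozen=True)
class ModelSpec:
    """Named covariate set for one outcome; reference levels are encoded in the dummies."""

    name: str
    outcome: str  # "mortality" | "unfavourable"
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.outcome not in ("mortality", "unfavourable"):
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")


_MODEL_COVARIATES = {
    "model1_gcs_hs": ("age", "male", "gcs", "hs_one", "hs_two", "hs_three_plus", "public", "emergency"),
    "model2_apache": ("male", "apache2", "public", "emergency"),
    "model3_saps3": ("male", "saps3", "public", "emergency"),
    "model4_sofa": ("age", "male", "sofa", "public", "emergency"),
}

MODEL_SPECS: tuple[ModelSpec, ...] = tuple(
    ModelSpec(name=name, outcome=outcome, covariates=cov)
    for name, cov in _MODEL_COVARIATES.items()
    for outcome in ("mortality", "unfavourable")
)


def _outcome_vector(frame: pd.DataFrame, outcome: str) -> pd.Series:
    if outcome == "mortality":
        return frame["died"].astype("boolean")
    return frame["unfavourable"]


def build_design(frame: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    """Numeric design matrix with Hs-category dummies (reference: zero Hs)."""
    cols = {}
    for cov in covariates:
        if cov.startswith("hs_") and cov != "hs_count":
            level = cov[3:]
            if "hs_category" not in frame.columns:
                raise ConfigurationError("cohort frame lacks 'hs_category'")
            cols[cov] = (frame["hs_category"] == level).astype(float)
        else:
            if cov not in frame.columns:
                raise ConfigurationError(f"cohort frame lacks column {cov!r}")
            cols[cov] = frame[cov].astype("Float64").astype(float)
    return pd.DataFrame(cols, index=frame.index)


def run_model(frame: pd.DataFrame, spec: ModelSpec, tol: float = 1e-10, max_iter: int = 100) -> FitResult:
    """Fit one specification on complete cases; attaches the in-sample ROC AUC."""
    y = _outcome_vector(frame, spec.outcome)
    X = build_design(frame, spec.covariates)
    keep = y.notna().to_numpy() & X.notna().all(axis=1).to_numpy()
    Xc = X.loc[keep]
    yc = y[keep].astype(bool).to_numpy().astype(float)
    fit = fit_logistic(Xc, yc, tol=tol, max_iter=max_iter)
    fit.n_dropped = int(len(frame) - keep.sum())
    fit.name = spec.name
    fit.outcome = spec.outcome
    coefs = fit.table["coef"].to_numpy()
    design = np.column_stack([np.ones(keep.sum()), Xc.to_numpy(dtype=float)])
    scores = 1 / (1 + np.exp(-(design @ coefs)))
    fit.auc = auc(scores, yc)
    return fit


def run_model_suite(frame: pd.DataFrame, specs: tuple[ModelSpec, ...] = MODEL_SPECS) -> list[FitResult]:
    """Fit every requested specification, reporting per-model complete-case counts."""
    return [run_model(frame, spec) for spec in specs]


def tidy_results(fits: list[FitResult]) -> pd.DataFrame:
    """Stack fit tables into one tidy frame (model, outcome, term, estimates, n, AUC)."""
    parts = []
    for fit in fits:
        t = fit.table.reset_index()
        t.insert(0, "model", fit.name)
        t.insert(1, "outcome", fit.outcome)
        t["n_used"] = fit.n_used
        t["n_dropped"] = fit.n_dropped
        t["converged"] = fit.converged
        t["auc"] = fit.auc
        parts.append(t)
    return pd.concat(parts, ignore_index=True)
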