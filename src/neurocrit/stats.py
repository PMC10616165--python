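"""Prognostic statistics: 2x2 odds ratios, logistic regression by IRLS, ROC AUC.

Inference is Wald-based throughout: confidence intervals are
``exp(log estimate +/- z * SE)`` on the log-odds scale and p-values come from
the normal approximation to the Wald z statistic — the convention of the
descriptive ICU-prognosis literature this package serves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import DomainError

__all__ = [
    "TwoByTwo",
    "ORResult",
    "FitResult",
    "DegenerateTableError",
    "SeparationError",
    "odds_ratio",
    "fit_logistic",
    "auc",
    "chi_square_homogeneity",
    "proportion",
]


class DegenerateTableError(ValueError):
    """A contingency table has a zero cell or margin that the analysis cannot use."""


class SeparationError(RuntimeError):
    """The logistic likelihood is maximized at infinity (perfect separation)."""


@dataclass(frozen=True)
class TwoByTwo:
    """Event/non-event counts for an exposed and a reference group."""

    exposed_events: int
    exposed_nonevents: int
    ref_events: int
    ref_nonevents: int

    def __post_init__(self) -> None:
        cells = (self.exposed_events, self.exposed_nonevents, self.ref_events, self.ref_nonevents)
        if any(c < 0 for c in cells):
            raise DomainError(f"counts must be non-negative, got {cells}")
        if sum(cells) == 0:
            raise DomainError("table is empty")

    def cells(self) -> tuple[int, int, int, int]:
        return (self.exposed_events, self.exposed_nonevents, self.ref_events, self.ref_nonevents)


@dataclass(frozen=True)
class ORResult:
    or_point: float
    ci_low: float
    ci_high: float
    p_wald: float
    zero_cell_corrected: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate and be positive")


def odds_ratio(t: TwoByTwo, alpha: float = 0.05, zero_cell_policy: str = "error") -> ORResult:
    """Unadjusted odds ratio with Wald CI and p-value from a 2x2 table.

    ``OR = (exposed_events * ref_nonevents) / (exposed_nonevents * ref_events)``;
    ``SE(log OR) = sqrt(sum of reciprocal cells)``.  With a zero cell the
    default policy raises :class:`DegenerateTableError`; policy ``"haldane"``
    adds 0.5 to every cell and flags the result.
    """
    a, b, c, d = (float(x) for x in t.cells())
    corrected = False
    if 0.0 in (a, b, c, d):
        if zero_cell_policy == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            corrected = True
        else:
            names = ("exposed_events", "exposed_nonevents", "ref_events", "ref_nonevents")
            zero = [n for n, v in zip(names, t.cells()) if v == 0]
            raise DegenerateTableError(f"zero cell(s) {zero}; use zero_cell_policy='haldane'")
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    p = 2 * sps.norm.sf(abs(log_or) / se)
    return ORResult(
        or_point=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p_wald=float(p),
        zero_cell_corrected=corrected,
    )


@dataclass
class FitResult:
    """A fitted logistic model: per-term estimates plus fit diagnostics.

    ``table`` has one row per term (including the intercept) with columns
    ``coef, se, or_, ci_low, ci_high, p_wald``.  ``n_used`` counts the
    complete cases actually fitted; ``n_dropped`` the rows removed for
    missingness.  ``auc`` is filled by the model suite, not by the fitter.
    """

    table: pd.DataFrame
    n_used: int
    converged: bool
    loglik: float
    n_dropped: int = 0
    auc: float | None = None
    name: str | None = None
    outcome: str | None = None

    def or_for(self, term: str) -> tuple[float, float, float]:
        row = self.table.loc[term]
        return float(row["or_"]), float(row["ci_low"]), float(row["ci_high"])


def fit_logistic(
    design: pd.DataFrame,
    outcome: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
    alpha: float = 0.05,
    add_intercept: bool = True,
) -> FitResult:
    """Maximum-likelihood logistic regression by IRLS (Newton-Raphson).

    ``design`` is a numeric DataFrame of covariates (an intercept column is
    prepended unless ``add_intercept=False``); ``outcome`` a 0/1 vector.
    Iteration stops when the relative change in log-likelihood falls below
    ``tol``.  Wald standard errors come from the inverse observed information
    at the optimum.  Perfect separation is declared when any coefficient
    exceeds 30 in absolute value and raises :class:`SeparationError`.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DomainError("design and outcome shapes disagree")
    if np.isnan(X).any() or np.isnan(y).any():
        raise DomainError("design/outcome contain missing values; drop incomplete rows first")
    if y.min() == y.max():
        raise DomainError("outcome is constant; logistic model undefined")
    names = list(design.columns)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + names

    beta = np.zeros(X.shape[1])
    eta = X @ beta
    mu = 1 / (1 + np.exp(-eta))
    loglik = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    converged = False
    for _ in range(max_iter):
        W = mu * (1 - mu)
        info = X.T @ (X * W[:, None])
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 30:
            raise SeparationError(
                "coefficients diverged (|beta| > 30); data are likely perfectly separated"
            )
        eta = np.clip(X @ beta, -700, 700)
        mu = 1 / (1 + np.exp(-eta))
        mu = np.clip(mu, 1e-300, 1 - 1e-16)
        new_loglik = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
        if abs(new_loglik - loglik) <= tol * (abs(loglik) + 1e-12):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    W = mu * (1 - mu)
    info = X.T @ (X * W[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z975 = sps.norm.ppf(1 - alpha / 2)
    zstat = beta / se
    table = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "or_": np.exp(beta),
            "ci_low": np.exp(beta - z975 * se),
            "ci_high": np.exp(beta + z975 * se),
            "p_wald": 2 * sps.norm.sf(np.abs(zstat)),
        },
        index=pd.Index(names, name="term"),
    )
    return FitResult(table=table, n_used=len(y), converged=converged, loglik=loglik)


def auc(scores: np.ndarray, outcome: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2.

    Equals the probability that a randomly chosen event outranks a randomly
    chosen non-event.  Requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if s.shape != y.shape:
        raise DomainError("scores and outcome must have the same length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DomainError("AUC undefined: outcome has a single class")
    ranks = sps.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def chi_square_homogeneity(
    table: np.ndarray, pairwise: bool = False, alpha: float = 0.05
) -> dict:
    """Pearson chi-square test that the rows of an r x c count table share one distribution.

    With ``pairwise=True`` every pair of rows is re-tested on the corresponding
    2 x c sub-table (the table is subset, not re-partitioned) and the pairwise
    p-values are Bonferroni-adjusted by the number of pairs.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DomainError("need at least a 2x2 table")
    if (obs < 0).any():
        raise DomainError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero row or column margin")
    stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
    result = {"statistic": float(stat), "df": int(df), "p": float(p)}
    if pairwise:
        r = obs.shape[0]
        n_pairs = r * (r - 1) // 2
        comparisons = {}
        for i in range(r):
            for j in range(i + 1, r):
                sub = obs[[i, j], :]
                sub = sub[:, sub.sum(axis=0) > 0]
                s, pp, _, _ = sps.chi2_contingency(sub, correction=False)
                comparisons[(i, j)] = {
                    "statistic": float(s),
                    "p": float(pp),
                    "p_bonferroni": float(min(1.0, pp * n_pairs)),
                    "significant": bool(pp < alpha / n_pairs),
                }
        result["pairwise"] = comparisons
        result["n_pairs"] = n_pairs
    return result


def proportion(numerator: int, denominator: int) -> float:
    """Percentage ``100 * numerator / denominator`` reported to 1 decimal."""
    if denominator <= 0:
        raise DomainError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise DomainError("numerator must lie in [0, denominator]")
    return round(100.0 * numerator / denominator, 1)
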