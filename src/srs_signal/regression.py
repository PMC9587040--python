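"""Adjusted signal modelling: multiple logistic regression with forced
confounders and bidirectional stepwise drug selection.

The signal model regresses the event flag on forced-entry confounders —
sex (female vs male), age (≥60 vs <60) and eBMI class (obese and
underweight indicators against a normal reference) — plus drug-exposure
indicators chosen by forward/backward stepwise selection at a fixed
significance level.  Exponentiated coefficients are adjusted reporting
odds ratios (aROR) with Wald 95% intervals.  Likelihood-ratio tests drive
entry and removal (invariant to parameterization; a software package
using Wald-based stepping may differ in borderline steps).  Drugs used to
treat the outcome itself can be barred from selection.  Variance
inflation factors on the linear design matrix diagnose multicollinearity.

Fitting is Newton–Raphson/IRLS with step-halving, which makes the
log-likelihood non-decreasing across iterations; coefficients running
away beyond a fixed bound are reported as perfect separation, naming the
offending covariate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AnalysisCase
from .jader_io import fmt2

logger = logging.getLogger("srs_signal")

Z95 = 1.959963984540054
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
#: |coefficient| beyond this during iteration is treated as separation
#: (an odds ratio above e^30 ≈ 1e13 is not estimable from report counts).
SEPARATION_BOUND = 30.0

FORCED_TERMS = ("sex_female", "age_ge60", "ebmi_obese", "ebmi_underweight")
#: Drugs used to treat the outcome are barred from selection by default
#: (protopathic: their exposure follows the event rather than causing it).
DEFAULT_EXCLUDED = frozenset({"albumin tannate", "prednisolone", "loperamide"})


class SeparationError(RuntimeError):
    """Perfect separation detected; message names the covariate."""


@dataclass
class ModelSpec:
    """Stepwise signal-model specification."""
    forced_terms: tuple[str, ...] = FORCED_TERMS
    candidate_terms: tuple[str, ...] = ()
    alpha_enter: float = 0.05
    alpha_remove: float = 0.05
    excluded_candidates: frozenset[str] = DEFAULT_EXCLUDED

    def validate(self) -> None:
        overlap = set(self.forced_terms) & set(self.candidate_terms)
        if overlap:
            raise ValueError(f"terms both forced and candidate: {overlap}")
        if not 0.0 < self.alpha_enter <= self.alpha_remove < 1.0:
            raise ValueError("need 0 < alpha_enter <= alpha_remove < 1")


@dataclass
class LogisticFit:
    terms: list[str]                    # includes "intercept" first
    coefficients: np.ndarray
    standard_errors: np.ndarray
    aror: np.ndarray                    # exp(coefficient), per term
    aror_ci: np.ndarray                 # (k, 2) array of (low, high)
    p_values: np.ndarray                # two-sided Wald
    log_likelihood: float
    loglik_path: list[float]            # per-iteration, non-decreasing
    vif: Mapping[str, float] | None
    selected_drugs: list[str]
    converged: bool
    n: int


def build_design(analysis_cases: Sequence[AnalysisCase],
                 drug_terms: Sequence[str]) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix (confounder + drug indicator columns) and outcome."""
    n = len(analysis_cases)
    data = {
        "sex_female": np.fromiter((c.sex == "female" for c in analysis_cases),
                                  float, n),
        "age_ge60": np.fromiter((c.age_ge60 for c in analysis_cases),
                                float, n),
        "ebmi_obese": np.fromiter((c.ebmi_class == "obese"
                                   for c in analysis_cases), float, n),
        "ebmi_underweight": np.fromiter((c.ebmi_class == "underweight"
                                         for c in analysis_cases), float, n),
    }
    for drug in drug_terms:
        data[drug] = np.fromiter((drug in c.exposed_drugs
                                  for c in analysis_cases), float, n)
    y = np.fromiter((c.event for c in analysis_cases), float, n)
    return pd.DataFrame(data), y


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # stable log(1 + e^eta)
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(design: pd.DataFrame, outcome: np.ndarray,
                 tol: float = IRLS_TOL, max_iter: int = IRLS_MAX_ITER,
                 selected_drugs: Sequence[str] = (),
                 compute_vif_terms: bool = False) -> LogisticFit:
    """Maximum-likelihood logistic fit by IRLS with step-halving.

    ``design`` holds the non-intercept terms; an intercept is added
    internally.  Convergence is a coefficient change below ``tol``;
    step-halving keeps the log-likelihood non-decreasing.
    """
    names = list(design.columns)
    X = design.to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {k} terms")
    for j, name in enumerate(names):
        col = X[:, j]
        if col.min() == col.max():
            raise ValueError(f"constant covariate column {name!r}")
    Xd = np.column_stack([np.ones(n), X])
    all_names = ["intercept"] + names

    beta = np.zeros(k + 1)
    ll = _loglik(Xd @ beta, y)
    path = [ll]
    converged = False
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = Xd.T @ (y - mu)
        hess = Xd.T @ (Xd * w[:, None])
        try:
            delta = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(hess, grad, rcond=None)[0]
        step = 1.0
        for _ in range(40):
            candidate = beta + step * delta
            ll_new = _loglik(Xd @ candidate, y)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta_new = beta + step * delta
        over = np.abs(beta_new) > SEPARATION_BOUND
        if over.any():
            worst = int(np.argmax(np.abs(beta_new)))
            raise SeparationError(
                f"perfect separation suspected: coefficient for "
                f"{all_names[worst]!r} exceeded |{SEPARATION_BOUND}|")
        change = np.max(np.abs(beta_new - beta))
        beta = beta_new
        ll = ll_new
        path.append(ll)
        if change < tol:
            converged = True
            break

    eta = Xd @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = Xd.T @ (Xd * w[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    aror = np.exp(beta)
    ci = np.column_stack([np.exp(beta - Z95 * se), np.exp(beta + Z95 * se)])

    vif = None
    if compute_vif_terms and k >= 2:
        vif = compute_vif(design)
    return LogisticFit(all_names, beta, se, aror, ci, p, ll, path, vif,
                       list(selected_drugs), converged, n)


def lr_test(full: LogisticFit, reduced: LogisticFit) -> float:
    """Likelihood-ratio p-value for one added term (χ², 1 df)."""
    lr = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    return float(stats.chi2.sf(max(lr, 0.0), 1))


def stepwise_select(spec: ModelSpec, design: pd.DataFrame,
                    outcome: np.ndarray) -> LogisticFit:
    """Forward/backward stepwise drug selection around forced confounders.

    Starting from the forced terms, each round adds the eligible candidate
    with the smallest likelihood-ratio p-value if it is below
    ``alpha_enter``, then removes the included non-forced term with the
    largest p-value if it is at or above ``alpha_remove``; forced terms
    are never removed, ties break lexicographically, and the loop stops
    when a round changes nothing (or a term-set repeats).
    """
    spec.validate()
    eligible = [t for t in spec.candidate_terms
                if t not in spec.excluded_candidates]
    included: list[str] = []
    cache: dict[frozenset, LogisticFit] = {}

    def fit_terms(terms: Sequence[str]) -> LogisticFit:
        key = frozenset(terms)
        if key not in cache:
            cols = list(spec.forced_terms) + sorted(
                t for t in terms if t not in spec.forced_terms)
            cache[key] = fit_logistic(design[cols], outcome)
        return cache[key]

    seen: set[frozenset] = set()
    for _ in range(200):
        state = frozenset(included)
        if state in seen:
            logger.warning("stepwise selection cycled; stopping")
            break
        seen.add(state)
        changed = False

        current = fit_terms(list(spec.forced_terms) + included)
        best_p, best_term = math.inf, None
        for cand in sorted(set(eligible) - set(included)):
            trial = fit_terms(list(spec.forced_terms) + included + [cand])
            p = lr_test(trial, current)
            if p < best_p:     # sorted iteration makes ties lexicographic
                best_p, best_term = p, cand
        if best_term is not None and best_p < spec.alpha_enter:
            included.append(best_term)
            included.sort()
            changed = True
            logger.info("stepwise: + %s (LR p=%.4g)", best_term, best_p)

        if included:
            full = fit_terms(list(spec.forced_terms) + included)
            worst_p, worst_term = -math.inf, None
            for term in sorted(included):
                reduced = fit_terms([t for t in list(spec.forced_terms)
                                     + included if t != term])
                p = lr_test(full, reduced)
                if p > worst_p:
                    worst_p, worst_term = p, term
            if worst_term is not None and worst_p >= spec.alpha_remove:
                included.remove(worst_term)
                changed = True
                logger.info("stepwise: - %s (LR p=%.4g)", worst_term, worst_p)

        if not changed:
            break

    final_cols = list(spec.forced_terms) + sorted(included)
    return fit_logistic(design[final_cols], outcome,
                        selected_drugs=sorted(included),
                        compute_vif_terms=True)


def subset_by_sex(analysis_cases: Sequence[AnalysisCase],
                  drugs: Sequence[str] = ("lansoprazole", "aspirin"),
                  ) -> dict[str, LogisticFit]:
    """Fixed-term models per sex: age ≥60, eBMI indicators, given drugs.

    No stepwise selection; mirrors a subset analysis where the model
    equation is fixed a priori in both strata.
    """
    fits: dict[str, LogisticFit] = {}
    for sex in ("female", "male"):
        subset = [c for c in analysis_cases if c.sex == sex]
        design, y = build_design(subset, drugs)
        cols = ["age_ge60", "ebmi_obese", "ebmi_underweight"] + list(drugs)
        fits[sex] = fit_logistic(design[cols], y, selected_drugs=list(drugs),
                                 compute_vif_terms=True)
    return fits


def compute_vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per column, 1/(1−R²) of each term
    regressed linearly on all others (with intercept).

    Exact collinearity is reported as ``inf`` rather than raised.
    """
    names = list(design.columns)
    if len(names) < 2:
        raise ValueError("VIF needs at least two non-intercept terms")
    X = design.to_numpy(dtype=float)
    n = X.shape[0]
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        target = X[:, j]
        if target.min() == target.max():
            raise ValueError(f"constant covariate column {name!r}")
        others = np.column_stack(
            [np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((target - target.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        if 1.0 - r2 < 1e-12:
            out[name] = math.inf
        else:
            out[name] = 1.0 / (1.0 - r2)
    return out


def fit_to_frame(fit: LogisticFit, design: pd.DataFrame, outcome: np.ndarray,
                 population: str, forced: Sequence[str]) -> pd.DataFrame:
    """Report rows for one fitted model (aROR and CI to 2 decimals)."""
    y = np.asarray(outcome, dtype=bool)
    rows = []
    forced_set = set(forced)
    for i, term in enumerate(fit.terms):
        if term == "intercept":
            continue
        col = design[term].to_numpy(dtype=bool)
        vif = "" if fit.vif is None else fmt2(fit.vif.get(term))
        rows.append({
            "population": population,
            "term": term,
            "cases_with_term": int((col & y).sum()),
            "noncases_with_term": int((col & ~y).sum()),
            "coefficient": f"{fit.coefficients[i]:.4f}",
            "se": f"{fit.standard_errors[i]:.4f}",
            "aror": fmt2(fit.aror[i]),
            "ci_low": fmt2(fit.aror_ci[i, 0]),
            "ci_high": fmt2(fit.aror_ci[i, 1]),
            "p_value": f"{fit.p_values[i]:.4g}",
            "vif": vif,
            "forced": str(term in forced_set).lower(),
            "selected": str(term in fit.selected_drugs).lower(),
        })
    return pd.DataFrame(rows, columns=[
        "population", "term", "cases_with_term", "noncases_with_term",
        "coefficient", "se", "aror", "ci_low", "ci_high", "p_value",
        "vif", "forced", "selected"])
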