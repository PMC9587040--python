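"""Logistic fitting, stepwise selection, and collinearity diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srs_signal.cohort import AnalysisCase
from srs_signal.regression import (ModelSpec, SeparationError, build_design,
                                   compute_vif, fit_logistic, stepwise_select,
                                   subset_by_sex)


def _design_from_table(a, b, c, d):
    """Expand a 2x2 table into outcome and single-indicator design."""
    x = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    y = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    return pd.DataFrame({"drug": x}), y


def test_single_covariate_fit_equals_crude_odds_ratio():
    design, y = _design_from_table(128, 33, 2238, 22444)
    fit = fit_logistic(design, y)
    crude = (128 * 22444) / (33 * 2238)
    assert math.exp(fit.coefficients[1]) == pytest.approx(crude, rel=1e-6)


def test_crude_or_identity_on_random_tables():
    rng = np.random.default_rng(77)
    for _ in range(50):
        a, b, c, d = rng.integers(5, 120, size=4)
        design, y = _design_from_table(int(a), int(b), int(c), int(d))
        fit = fit_logistic(design, y)
        crude = (a * d) / (b * c)
        assert math.exp(fit.coefficients[1]) == pytest.approx(crude, rel=1e-6)


def test_intercept_only_closed_form():
    y = np.array([1.0] * 30 + [0.0] * 70)
    fit = fit_logistic(pd.DataFrame(index=range(100)), y)
    b0 = fit.coefficients[0]
    assert math.exp(b0) / (1 + math.exp(b0)) == pytest.approx(0.3, rel=1e-8)


def test_agreement_with_statsmodels():
    import statsmodels.api as sm
    rng = np.random.default_rng(3)
    n = 2000
    X = pd.DataFrame({"x1": rng.random(n) < 0.3,
                      "x2": rng.random(n) < 0.5}).astype(float)
    eta = -2.0 + 1.2 * X.x1 - 0.7 * X.x2
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_logistic(X, y)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    np.testing.assert_allclose(fit.coefficients, ref.params, rtol=1e-6)
    np.testing.assert_allclose(fit.standard_errors, ref.bse, rtol=1e-5)
    np.testing.assert_allclose(fit.p_values[1:], ref.pvalues[1:], atol=1e-6)


def test_loglikelihood_never_decreases():
    rng = np.random.default_rng(9)
    n = 500
    X = pd.DataFrame({"x": (rng.random(n) < 0.4).astype(float)})
    y = (rng.random(n) < 0.2).astype(float)
    fit = fit_logistic(X, y)
    path = np.array(fit.loglik_path)
    assert np.all(np.diff(path) >= -1e-12)
    assert fit.converged


def test_separation_error_names_covariate():
    x = np.array([0.0] * 50 + [1.0] * 50)
    y = x.copy()
    noise = np.tile([0.0, 1.0], 50)
    design = pd.DataFrame({"benign": noise, "culprit": x})
    with pytest.raises(SeparationError, match="culprit"):
        fit_logistic(design, y)


def test_constant_column_rejected():
    with pytest.raises(ValueError, match="flat"):
        fit_logistic(pd.DataFrame({"flat": np.ones(50)}),
                     np.tile([0.0, 1.0], 25))


def test_null_pvalues_are_uniform():
    """Wald p-values under the global null pass a KS uniformity check."""
    rng = np.random.default_rng(41)
    pvals = []
    for _ in range(200):
        n = 600
        X = pd.DataFrame({
            "x1": (rng.random(n) < 0.3).astype(float),
            "x2": (rng.random(n) < 0.5).astype(float),
            "x3": (rng.random(n) < 0.1).astype(float)})
        y = (rng.random(n) < 0.3).astype(float)
        fit = fit_logistic(X, y)
        pvals.extend(fit.p_values[1:])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# -- VIF -------------------------------------------------------------------

def test_vif_orthogonal_columns():
    X = pd.DataFrame({"a": np.tile([0.0, 1.0], 50),
                      "b": np.repeat([0.0, 1.0], 50)})
    vif = compute_vif(X)
    assert vif["a"] == pytest.approx(1.0, abs=1e-12)
    assert vif["b"] == pytest.approx(1.0, abs=1e-12)


def test_vif_flags_exact_collinearity():
    x = np.tile([0.0, 1.0, 1.0, 0.0], 25)
    vif = compute_vif(pd.DataFrame({"a": x, "b": x}))
    assert math.isinf(vif["a"]) and math.isinf(vif["b"])


def test_vif_two_column_closed_form():
    rng = np.random.default_rng(15)
    x = rng.normal(size=400)
    z = 0.6 * x + rng.normal(size=400)
    X = pd.DataFrame({"x": x, "z": z})
    r = np.corrcoef(x, z)[0, 1]
    expected = 1.0 / (1.0 - r * r)
    vif = compute_vif(X)
    assert vif["x"] == pytest.approx(expected, abs=1e-9)
    assert vif["z"] == pytest.approx(expected, abs=1e-9)


# -- stepwise and subsets --------------------------------------------------

def _synthetic_cases(rng, n, drug_effects, drug_probs):
    cases = []
    for i in range(n):
        female = rng.random() < 0.5
        ge60 = rng.random() < 0.5
        drugs = {d for d, p in drug_probs.items() if rng.random() < p}
        eta = (math.log(0.08 / 0.92) + 0.8 * female + 0.9 * ge60
               + sum(drug_effects.get(d, 0.0) for d in drugs))
        event = rng.random() < 1 / (1 + math.exp(-eta))
        cases.append(AnalysisCase(
            f"s{i}", "female" if female else "male",
            "60-69" if ge60 else "50-59", ge60,
            float(rng.choice([17.0, 20.0, 27.0])), "", frozenset(drugs),
            bool(event), None))
    return [AnalysisCase(c.case_id, c.sex, c.age_band, c.age_ge60, c.ebmi,
                         ("underweight" if c.ebmi < 18.5 else
                          "normal" if c.ebmi < 25 else "obese"),
                         c.exposed_drugs, c.event, c.outcome)
            for c in cases]


def test_stepwise_with_no_candidates_equals_forced_fit():
    rng = np.random.default_rng(55)
    cases = _synthetic_cases(rng, 2000, {}, {"a": 0.1})
    design, y = build_design(cases, ["a"])
    spec = ModelSpec(candidate_terms=(), excluded_candidates=frozenset())
    stepped = stepwise_select(spec, design, y)
    direct = fit_logistic(design[list(spec.forced_terms)], y)
    assert stepped.selected_drugs == []
    np.testing.assert_allclose(stepped.coefficients, direct.coefficients,
                               atol=1e-10)


def test_excluded_candidates_never_selected():
    rng = np.random.default_rng(66)
    cases = _synthetic_cases(rng, 4000, {"treat": math.log(30.0)},
                             {"treat": 0.1})
    design, y = build_design(cases, ["treat"])
    spec = ModelSpec(candidate_terms=("treat",),
                     excluded_candidates=frozenset({"treat"}))
    fit = stepwise_select(spec, design, y)
    assert fit.selected_drugs == []


def test_stepwise_selects_injected_drugs():
    rng = np.random.default_rng(88)
    probs = {f"null{i}": 0.08 for i in range(8)}
    probs.update({"big": 0.08, "mid": 0.1})
    effects = {"big": math.log(20.0), "mid": math.log(2.5)}
    cases = _synthetic_cases(rng, 8000, effects, probs)
    drugs = sorted(probs)
    design, y = build_design(cases, drugs)
    spec = ModelSpec(candidate_terms=tuple(drugs),
                     excluded_candidates=frozenset())
    fit = stepwise_select(spec, design, y)
    assert {"big", "mid"} <= set(fit.selected_drugs)
    assert fit.vif is not None
    assert all(v < 2 for v in fit.vif.values())


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(forced_terms=("a",), candidate_terms=("a",)).validate()
    with pytest.raises(ValueError):
        ModelSpec(alpha_enter=0.1, alpha_remove=0.05).validate()


def test_sex_subsets_are_symmetric_for_duplicated_data():
    rng = np.random.default_rng(23)
    base = _synthetic_cases(rng, 3000, {"d": math.log(5.0)}, {"d": 0.15})
    mirrored = []
    for sex in ("female", "male"):
        for c in base:
            mirrored.append(AnalysisCase(
                f"{sex}_{c.case_id}", sex, c.age_band, c.age_ge60, c.ebmi,
                c.ebmi_class, c.exposed_drugs, c.event, c.outcome))
    fits = subset_by_sex(mirrored, drugs=("d",))
    np.testing.assert_allclose(fits["female"].coefficients,
                               fits["male"].coefficients, atol=1e-6)
    n_f = fits["female"].n
    n_m = fits["male"].n
    assert n_f + n_m == len(mirrored)
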