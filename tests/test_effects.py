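"""Variance-covariance bootstrap of percentage effects."""

import numpy as np
import pandas as pd
import pytest

from pollidiv.effects import (EffectConfig, class_rows_for_factor,
                              draw_fixed_effects, effects_as_percent,
                              effects_table, interaction_significance,
                              predict_gradient)
from pollidiv.models import Design, F, Ix, ModelFit, ModelSpec, N
from pollidiv.mixed import MixedResult


def make_fit(labels, beta, vcov, family="poisson", design_terms=None,
             levels=None):
    """Hand-assembled ModelFit with a chosen coefficient vector/covariance."""
    design = Design(design_terms or [])
    design.labels = list(labels)
    design.levels = levels or {}
    n = 10
    result = MixedResult(
        beta=np.asarray(beta, float), vcov=np.asarray(vcov, float),
        loglik=0.0, aic=0.0, family=family, var_components={},
        resid_var=1.0 if family == "gaussian" else None, ranef={},
        group_names=("SS",), n_obs=n, n_params=len(beta),
        fitted=np.zeros(n), residuals=np.zeros(n), converged=True)
    spec = ModelSpec("richness" if family == "poisson" else "abundance_ln1p",
                     design_terms or [])
    return ModelFit(spec=spec, design=design, result=result,
                    random=("SS",), olre=False, data_index=pd.RangeIndex(n))


def lui_fit(beta_class, family="poisson", v=0.0):
    fit = make_fit(
        ["(Intercept)", "LUI=Urban_Intense"], [np.log(11.0), beta_class],
        np.eye(2) * v, family=family,
        design_terms=[F("LUI", "Primary_Minimal")],
        levels={"LUI": ["Urban_Intense"]})
    return fit


def test_zero_variance_draws_equal_beta():
    fit = lui_fit(0.5)
    draws = draw_fixed_effects(fit, EffectConfig(n_draws=50, seed=1))
    assert np.allclose(draws, fit.result.beta)


def test_draw_covariance_matches_v():
    V = np.array([[0.04, 0.01], [0.01, 0.09]])
    fit = make_fit(["(Intercept)", "b"], [1.0, 2.0], V)
    draws = draw_fixed_effects(fit, EffectConfig(n_draws=100_000, seed=2))
    assert np.allclose(np.cov(draws.T), V, atol=2e-3)
    assert np.allclose(draws.mean(0), [1.0, 2.0], atol=2e-3)


def test_draws_seeded_and_reproducible():
    V = np.eye(2) * 0.1
    fit = make_fit(["(Intercept)", "b"], [0.0, 0.0], V)
    d1 = draw_fixed_effects(fit, EffectConfig(n_draws=100, seed=7))
    d2 = draw_fixed_effects(fit, EffectConfig(n_draws=100, seed=7))
    d3 = draw_fixed_effects(fit, EffectConfig(n_draws=100, seed=8))
    assert np.array_equal(d1, d2)
    assert not np.array_equal(d1, d3)


def test_nonfinite_vcov_rejected():
    fit = make_fit(["(Intercept)"], [1.0], [[np.inf]])
    with pytest.raises(ValueError):
        draw_fixed_effects(fit, EffectConfig())


def pct_for(fit, config=None):
    config = config or EffectConfig(n_draws=200, seed=3)
    cr, br, labels = class_rows_for_factor(fit, "LUI", "Primary_Minimal")
    return {e.label: e for e in effects_as_percent(fit, cr, br, labels,
                                                   config)}


def test_log_link_closed_form_percentages():
    # V = 0: percentage is exactly 100 * exp(beta_class)
    assert pct_for(lui_fit(0.0))["Urban_Intense"].median_pct \
        == pytest.approx(100.0)
    assert pct_for(lui_fit(np.log(2)))["Urban_Intense"].median_pct \
        == pytest.approx(200.0)
    est = pct_for(lui_fit(-0.7))["Urban_Intense"]
    assert est.median_pct == pytest.approx(100 * np.exp(-0.7))
    assert est.lower_pct == est.median_pct == est.upper_pct


def test_gaussian_backtransform_worked_example():
    # baseline eta = ln 11, class eta = ln 6: (6-1)/(11-1) * 100 = 50%
    fit = lui_fit(np.log(6.0) - np.log(11.0), family="gaussian")
    est = pct_for(fit)["Urban_Intense"]
    assert est.median_pct == pytest.approx(50.0, abs=1e-9)
    # sensitivity variant: plain exp ratio = 6/11
    alt = pct_for(fit, EffectConfig(n_draws=50, seed=3,
                                    backtransform="exp"))["Urban_Intense"]
    assert alt.median_pct == pytest.approx(100 * 6 / 11, abs=1e-9)


def test_baseline_class_anchored_at_100():
    est = pct_for(lui_fit(-0.3, v=0.05))["Primary_Minimal"]
    assert est.median_pct == pytest.approx(100.0)
    assert est.lower_pct == pytest.approx(100.0)


def test_percentiles_ordered_and_config_validated():
    est = pct_for(lui_fit(-0.3, v=0.04))["Urban_Intense"]
    assert est.lower_pct <= est.median_pct <= est.upper_pct
    with pytest.raises(ValueError):
        EffectConfig(percentiles=(97.5, 2.5))


def test_effects_table_shape():
    tab = effects_table(list(pct_for(lui_fit(-0.3)).values()))
    assert list(tab.columns[:4]) == ["class", "median", "lower", "upper"]
    assert len(tab) == 2


def gradient_fit(slope, v=0.0):
    return make_fit(
        ["(Intercept)", "log10fert"], [1.0, slope], np.eye(2) * v,
        design_terms=[N("log10fert")])


def test_gradient_flat_when_slope_zero():
    data = pd.DataFrame({"log10fert": np.linspace(0, 3, 40),
                         "Order": "Diptera"})
    curves = predict_gradient(gradient_fit(0.0), data, "log10fert", "Order",
                              EffectConfig(n_draws=20, seed=1))
    assert np.allclose(curves["median"], curves["median"].iloc[0])
    assert curves["pct_change_over_range"].iloc[0] == pytest.approx(100.0)


def test_gradient_monotone_for_positive_slope():
    data = pd.DataFrame({"log10fert": np.linspace(0, 3, 40),
                         "Order": "Diptera"})
    curves = predict_gradient(gradient_fit(0.8), data, "log10fert", "Order",
                              EffectConfig(n_draws=20, seed=1))
    assert (np.diff(curves["median"]) > 0).all()
    assert curves["pct_change_over_range"].iloc[0] > 100.0


def test_gradient_skips_small_strata():
    data = pd.DataFrame({"log10fert": [1.0] * 5, "Order": "Apodiformes"})
    curves = predict_gradient(gradient_fit(0.5), data, "log10fert", "Order",
                              EffectConfig(n_draws=20, seed=1), min_sites=10)
    assert curves.empty


def test_interaction_significance_tails():
    labels = ["(Intercept)", "log10fert", "Order=Diptera",
              "log10fert:Order=Diptera"]
    V = np.eye(4)
    fit = make_fit(labels, [0, 0, 0, 0.0], V)
    tab = interaction_significance(fit).set_index("coef")
    assert tab.loc["log10fert:Order=Diptera", "p"] == pytest.approx(1.0)
    fit = make_fit(labels, [0, 0, 0, 5.0], V)
    tab = interaction_significance(fit).set_index("coef")
    assert tab.loc["log10fert:Order=Diptera", "p"] < 1e-6
    assert bool(tab.loc["log10fert:Order=Diptera", "significant"])
    with pytest.raises(ValueError):
        interaction_significance(gradient_fit(0.0))
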