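"""Mixed-model engine and model-selection machinery.

The estimation backend is internal; its agreement with independent
reference backends (statsmodels MixedLM for gaussian ML, lme4::glmer via
Rscript for the Poisson Laplace fit) is itself part of the contract and
tested here on small datasets.
"""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

from pollidiv.mixed import fit_glmm_poisson, fit_lmm
from pollidiv.models import (F, ModelSpec, anova_terms, check_overdispersion,
                             fit_mixed, gate_against_null,
                             select_random_structure)


def nested_design(rng, n_studies=20, n_blocks=3, n_per=10):
    study = np.repeat(np.arange(n_studies), n_blocks * n_per)
    block = np.repeat(np.arange(n_studies * n_blocks), n_per)
    return study, block


# --- gaussian engine --------------------------------------------------------

def test_lmm_matches_dense_likelihood_and_statsmodels(rng):
    study, block = nested_design(rng)
    n = len(study)
    x = rng.binomial(1, 0.4, n)
    y = (2.0 - 0.5 * x + rng.normal(0, 0.5, 20)[study]
         + rng.normal(0, 0.3, 60)[block] + rng.normal(0, 0.7, n))
    X = np.column_stack([np.ones(n), x])
    fit = fit_lmm(y, X, {"SS": study, "SSB": block})

    # dense-matrix marginal log-likelihood at the fitted parameters
    from scipy.stats import multivariate_normal
    V = (fit.var_components["SS"] * (study[:, None] == study[None, :])
         + fit.var_components["SSB"] * (block[:, None] == block[None, :])
         + fit.resid_var * np.eye(n))
    dense_ll = multivariate_normal.logpdf(y, X @ fit.beta, V)
    assert fit.loglik == pytest.approx(dense_ll, abs=1e-6)

    # score equation: X' V^-1 (y - X beta) = 0 at the ML solution
    score = X.T @ np.linalg.solve(V, y - X @ fit.beta)
    assert np.allclose(score, 0.0, atol=1e-6)

    import statsmodels.api as sm
    df = pd.DataFrame(dict(y=y, x=x, SS=study, SSB=block))
    ref = sm.MixedLM.from_formula(
        "y ~ x", groups="SS", re_formula="1",
        vc_formula={"SSB": "0 + C(SSB)"}, data=df).fit(reml=False)
    assert fit.beta == pytest.approx(ref.fe_params.values, abs=1e-3)
    # our optimum should be at least as good as the reference's
    assert fit.loglik >= ref.llf - 1e-4


def test_lmm_intercept_only_constant_response(rng):
    study, block = nested_design(rng, n_studies=5, n_blocks=2, n_per=5)
    y = np.full(len(study), 3.7)
    fit = fit_lmm(y, np.ones((len(study), 1)), {"SS": study})
    assert fit.beta[0] == pytest.approx(3.7, abs=1e-8)
    assert fit.se[0] == pytest.approx(0.0, abs=1e-8)   # no variance anywhere


def test_lmm_gaussian_parameter_recovery(rng):
    """Planted ln(0.6) class effect recovered within +-3 SE."""
    study, block = nested_design(rng, n_studies=25, n_blocks=2, n_per=10)
    n = len(study)
    x = rng.binomial(1, 0.5, n)          # ~250 sites in the affected class
    y = (3.0 + np.log(0.6) * x + rng.normal(0, 0.4, 25)[study]
         + rng.normal(0, 0.2, 50)[block] + rng.normal(0, 0.5, n))
    fit = fit_lmm(y, np.column_stack([np.ones(n), x]),
                  {"SS": study, "SSB": block})
    assert abs(fit.beta[1] - np.log(0.6)) < 3 * fit.se[1]


# --- poisson engine ---------------------------------------------------------

def simulate_poisson(rng, disp=None, n_studies=20, n_per=12, beta=(1.6, -0.4)):
    study = np.repeat(np.arange(n_studies), n_per)
    n = len(study)
    x = rng.binomial(1, 0.5, n)
    eta = beta[0] + beta[1] * x + rng.normal(0, 0.4, n_studies)[study]
    if disp is not None:                     # NB overdispersion
        m = np.exp(eta)
        y = rng.negative_binomial(disp, disp / (disp + m))
    else:
        y = rng.poisson(np.exp(eta))
    X = np.column_stack([np.ones(n), x])
    return y.astype(float), X, study, x


def test_glmm_poisson_agrees_with_lme4(rng, tmp_path):
    """Cross-check slope, SEs and variance components against glmer."""
    y, X, study, x = simulate_poisson(rng)
    fit = fit_glmm_poisson(y, X, {"SS": study})
    df = pd.DataFrame(dict(y=y.astype(int), x=x, SS=study))
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rscript = tmp_path / "fit.R"
    rscript.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(y ~ x + (1|SS), data=d, family=poisson)
        out <- c(fixef(m), sqrt(diag(as.matrix(vcov(m)))),
                 as.data.frame(VarCorr(m))$vcov, AIC(m))
        cat(paste(out, collapse=","))
    """))
    res = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                         text=True, timeout=300)
    assert res.returncode == 0, res.stderr
    b0, b1, se0, se1, vc, aic = map(float, res.stdout.strip().split(","))
    assert fit.beta[1] == pytest.approx(b1, abs=0.02)
    assert fit.se[1] == pytest.approx(se1, rel=0.05)
    assert fit.var_components["SS"] == pytest.approx(vc, rel=0.10, abs=0.01)
    assert fit.aic == pytest.approx(aic, rel=0.01)


def test_overdispersion_ratio_near_one_for_poisson_data(rng):
    y, X, study, _ = simulate_poisson(rng, n_studies=40, n_per=25)
    df = pd.DataFrame({"richness": y, "SS": study, "SSB": study,
                       "x": X[:, 1]})
    fit = fit_mixed(ModelSpec("richness", [N_x()]), df, random=("SS",))
    assert check_overdispersion(fit) == pytest.approx(1.0, abs=0.15)


def test_overdispersion_detected_and_absorbed_by_olre(rng):
    y, X, study, x = simulate_poisson(rng, disp=1.0, n_studies=40, n_per=25)
    df = pd.DataFrame({"richness": y, "SS": study, "x": x})
    plain = fit_mixed(ModelSpec("richness", [N_x()]), df, random=("SS",))
    assert check_overdispersion(plain) > 1.5
    with_olre = fit_mixed(ModelSpec("richness", [N_x()]), df, random=("SS",),
                          olre=True)
    # the OLRE absorbs the extra-Poisson variation: no residual
    # overdispersion remains (the log-normal OLRE slightly over-matches
    # the NB variance at its ML, so the ratio can fall below 1)
    assert check_overdispersion(with_olre) < 1.2
    assert with_olre.aic < plain.aic


def N_x():
    from pollidiv.models import N
    return N("x")


def test_poisson_rejects_negative_or_gaussian_misuse(rng):
    with pytest.raises(ValueError):
        fit_glmm_poisson(np.array([-1.0, 2.0]), np.ones((2, 1)),
                         {"SS": np.array([0, 1])})
    df = pd.DataFrame({"abundance_ln1p": [1.0, 2.0, 1.5, 2.5],
                       "SS": [0, 0, 1, 1]})
    with pytest.raises(ValueError):
        fit_mixed(ModelSpec("abundance_ln1p", []), df, random=("SS",),
                  olre=True)
    gfit = fit_mixed(ModelSpec("abundance_ln1p", []), df, random=("SS",))
    with pytest.raises(ValueError):
        check_overdispersion(gfit)


# --- structure selection and gating ----------------------------------------

def test_select_random_structure_single_candidate(rng):
    y, X, study, x = simulate_poisson(rng, n_studies=10)
    df = pd.DataFrame({"richness": y, "SS": study, "x": x})
    fit = select_random_structure(ModelSpec("richness", [N_x()]), df,
                                  [(("SS",), False)])
    assert fit.random == ("SS",)


def test_select_random_structure_prefers_simpler_on_tie(rng):
    """Zero block variance: the spurious extra term cannot win."""
    study, block = nested_design(rng, n_studies=15, n_blocks=2, n_per=10)
    n = len(study)
    y = 2.0 + rng.normal(0, 0.5, 15)[study] + rng.normal(0, 0.6, n)
    df = pd.DataFrame({"abundance_ln1p": y, "SS": study, "SSB": block})
    spec = ModelSpec("abundance_ln1p", [])
    fit = select_random_structure(spec, df,
                                  [(("SS",), False), (("SS", "SSB"), False)])
    two = fit_mixed(spec, df, random=("SS", "SSB"))
    if abs(fit.aic - two.aic) < 2.5:      # block variance collapsed to ~0
        assert fit.random == ("SS",)
    # deterministic given data and candidate order
    again = select_random_structure(spec, df,
                                    [(("SS",), False), (("SS", "SSB"), False)])
    assert again.random == fit.random and again.aic == fit.aic


class _FakeFit:
    def __init__(self, response, aic):
        self.spec = ModelSpec(response, [])
        self.aic = aic


@pytest.mark.parametrize("main,null,decision", [
    (100.0, 90.0, "discard"), (90.0, 100.0, "keep"), (95.0, 95.0, "keep"),
])
def test_gate_against_null_rule(main, null, decision):
    assert gate_against_null(_FakeFit("richness", main),
                             _FakeFit("richness", null)) == decision


def test_gate_requires_same_response():
    with pytest.raises(ValueError):
        gate_against_null(_FakeFit("richness", 1.0),
                          _FakeFit("chao1", 2.0))


# --- per-term Wald tests ----------------------------------------------------

def test_anova_terms_shapes_and_errors(rng):
    study, _ = nested_design(rng, n_studies=12, n_blocks=1, n_per=20)
    n = len(study)
    lu = rng.choice(["Primary", "Crop", "Urban"], n)
    it = rng.choice(["Minimal", "Intense"], n)
    y = 2.0 + 0.5 * (lu == "Urban") + rng.normal(0, 0.5, 12)[study] \
        + rng.normal(0, 0.4, n)
    df = pd.DataFrame({"abundance_ln1p": y, "SS": study,
                       "Predominant_land_use": lu, "Use_intensity": it})
    fit = fit_mixed(ModelSpec("abundance_ln1p",
                              [F("Predominant_land_use", "Primary"),
                               F("Use_intensity", "Minimal")]),
                    df, random=("SS",))
    tab = anova_terms(fit).set_index("term")
    assert (tab.F >= 0).all()
    assert tab.loc["Predominant_land_use", "ndf"] == 2
    assert tab.loc["Predominant_land_use", "p"] < 0.05   # planted effect
    # single-level factor refused
    df1 = df.assign(Use_intensity="Minimal")
    with pytest.raises(ValueError):
        fit_mixed(ModelSpec("abundance_ln1p",
                            [F("Use_intensity", "Minimal")]), df1,
                  random=("SS",))
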