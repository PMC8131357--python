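"""Model specification and fitting for the land-use-intensity analyses.

Responses and families follow the analysis design: species richness and
Chao1 richness are Poisson log-link GLMMs (Chao1 rounded to the nearest
integer and treated quasi-likelihood-wise); total abundance and Simpson
diversity are gaussian LMMs on the ln(x+1) scale. Random-intercept
candidates are study, spatial block within study, and — Poisson models
only — an observation-level (site) intercept absorbing overdispersion.
Random structures are chosen to minimise AIC; every main model is gated
against an intercept-only null and discarded if its AIC is higher.

The fixed-effects design is built by a small explicit builder
(:class:`F`, :class:`N`, :class:`Ix` terms) so coefficient labels are
predictable ("LUI=Urban_Intense", "log10fert:Order=Diptera"), which the
effect-bootstrap stage relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixed import MixedResult, fit_glmm_poisson, fit_lmm, ConvergenceError

__all__ = [
    "F", "N", "Ix", "Design", "ModelSpec", "ModelFit", "fit_mixed",
    "select_random_structure", "gate_against_null", "check_overdispersion",
    "anova_terms", "RESPONSE_FAMILIES",
]

log = logging.getLogger(__name__)

RESPONSE_FAMILIES = {
    "richness": "poisson",
    "chao1": "poisson",
    "abundance_ln1p": "gaussian",
    "simpson_ln1p": "gaussian",
}


# ---------------------------------------------------------------------------
# fixed-effects design terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class F:
    """Categorical factor with a reference level (treatment coding)."""
    col: str
    ref: str


@dataclass(frozen=True)
class N:
    """Numeric covariate."""
    col: str


@dataclass(frozen=True)
class Ix:
    """Interaction of two terms."""
    a: object
    b: object


class Design:
    """Fixed-effects design matrix builder with stable labels.

    Levels are captured at fit time; prediction rows for new data reuse
    them, so a class emptied by a refit keeps its position dropped rather
    than shifting labels.
    """

    def __init__(self, terms):
        self.terms = list(terms)
        self.levels: dict[str, list] = {}
        self.labels: list[str] | None = None

    def _cols_for(self, term, df, capture):
        if isinstance(term, F):
            if capture:
                obs = [l for l in pd.unique(df[term.col]) if l != term.ref]
                self.levels[term.col] = sorted(map(str, obs))
            cols, labels = [], []
            for level in self.levels[term.col]:
                cols.append((df[term.col].astype(str) == level)
                            .to_numpy(float))
                labels.append(f"{term.col}={level}")
            return cols, labels
        if isinstance(term, N):
            return [df[term.col].to_numpy(float)], [term.col]
        if isinstance(term, Ix):
            ca, la = self._cols_for(term.a, df, capture=False)
            cb, lb = self._cols_for(term.b, df, capture=False)
            cols, labels = [], []
            for xa, na in zip(ca, la):
                for xb, nb in zip(cb, lb):
                    cols.append(xa * xb)
                    labels.append(f"{na}:{nb}")
            return cols, labels
        raise TypeError(f"unknown term {term!r}")

    def build(self, df: pd.DataFrame, capture: bool = False):
        if capture:
            def capture_levels(t):
                if isinstance(t, F):
                    obs = [str(l) for l in pd.unique(df[t.col])
                           if str(l) != t.ref]
                    self.levels[t.col] = sorted(obs)
                elif isinstance(t, Ix):
                    capture_levels(t.a)
                    capture_levels(t.b)
            for t in self.terms:
                capture_levels(t)
        cols = [np.ones(len(df))]
        labels = ["(Intercept)"]
        for t in self.terms:
            c, l = self._cols_for(t, df, capture=False)
            cols.extend(c)
            labels.extend(l)
        X = np.column_stack(cols)
        if capture:
            # drop empty columns (classes with no data) to keep full rank
            keep = [i for i in range(X.shape[1])
                    if i == 0 or np.any(X[:, i] != 0)]
            dropped = [labels[i] for i in range(X.shape[1]) if i not in keep]
            if dropped:
                log.info("design: dropping empty columns %s", dropped)
            X = X[:, keep]
            labels = [labels[i] for i in keep]
            self.labels = labels
        else:
            X = X[:, [i for i, l in enumerate(labels) if l in set(self.labels)]]
            labels = [l for l in labels if l in set(self.labels)]
        return X, labels

    def term_labels(self) -> dict:
        """term name -> list of coefficient labels, for per-term tests."""
        out: dict[str, list] = {}

        def name_of(t):
            if isinstance(t, F):
                return t.col
            if isinstance(t, N):
                return t.col
            return f"{name_of(t.a)}:{name_of(t.b)}"

        for t in self.terms:
            name = name_of(t)
            if isinstance(t, Ix):
                out[name] = [l for l in self.labels if ":" in l]
            elif isinstance(t, F):
                out[name] = [l for l in self.labels
                             if l.startswith(f"{t.col}=") and ":" not in l]
            else:
                out[name] = [l for l in self.labels if l == t.col]
        return out


# ---------------------------------------------------------------------------
# model spec / fit
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    response: str
    fixed: list = field(default_factory=list)   # [] = intercept-only null
    family: str | None = None                   # inferred from response

    def resolved_family(self) -> str:
        if self.family:
            return self.family
        try:
            return RESPONSE_FAMILIES[self.response]
        except KeyError:
            raise ValueError(f"unknown response {self.response!r}; give family")

    def null(self) -> "ModelSpec":
        return ModelSpec(response=self.response, fixed=[],
                         family=self.resolved_family())


@dataclass
class ModelFit:
    spec: ModelSpec
    design: Design
    result: MixedResult
    random: tuple                 # grouping factor columns used
    olre: bool
    data_index: pd.Index

    @property
    def beta(self) -> pd.Series:
        return pd.Series(self.result.beta, index=self.design.labels)

    @property
    def vcov(self) -> pd.DataFrame:
        return pd.DataFrame(self.result.vcov, index=self.design.labels,
                            columns=self.design.labels)

    @property
    def aic(self) -> float:
        return self.result.aic

    @property
    def converged(self) -> bool:
        return self.result.converged

    @property
    def family(self) -> str:
        return self.result.family

    def predict_eta(self, newdata: pd.DataFrame,
                    beta: np.ndarray | None = None) -> np.ndarray:
        """Population-level linear predictor rows for new data."""
        X, _ = self.design.build(newdata, capture=False)
        b = self.result.beta if beta is None else beta
        return X @ b

    def to_record(self) -> dict:
        """JSON-serialisable summary with deterministic field order."""
        return {
            "response": self.spec.response,
            "family": self.family,
            "labels": list(self.design.labels),
            "beta": [float(v) for v in self.result.beta],
            "vcov": [float(v) for v in self.result.vcov.ravel()],
            "aic": float(self.aic),
            "loglik": float(self.result.loglik),
            "random": list(self.random) + (["OLRE"] if self.olre else []),
            "var_components": {k: float(v) for k, v
                               in self.result.var_components.items()},
            "n_obs": int(self.result.n_obs),
            "converged": bool(self.converged),
            "singular": bool(self.result.singular),
        }


def fit_mixed(spec: ModelSpec, data: pd.DataFrame,
              random: tuple = ("SS", "SSB"), olre: bool = False) -> ModelFit:
    """Fit one mixed model; the estimation engine is the internal one.

    ``random`` names grouping columns (study, block-within-study); block
    labels are expected to be globally unique (the block id embeds the
    study id), giving the nested structure. Poisson responses are rounded
    to integers (relevant for Chao1, whose estimator is non-integer).
    """
    family = spec.resolved_family()
    design = Design(spec.fixed)
    X, labels = design.build(data, capture=True)
    for col in spec_columns(spec):
        if data[col].nunique() < 2 and isinstance_col(spec, col):
            raise ValueError(f"fixed factor {col} has a single level")
    y = data[spec.response].to_numpy(float)
    groups = {g: data[g].to_numpy() for g in random}
    if family == "poisson":
        yi = np.round(y)
        result = fit_glmm_poisson(yi, X, groups, olre=olre)
    else:
        if olre:
            raise ValueError("observation-level intercept requires poisson family")
        result = fit_lmm(y, X, groups)
    fit = ModelFit(spec=spec, design=design, result=result, random=random,
                   olre=olre, data_index=data.index)
    if not result.converged:
        log.warning("fit_mixed: %s model did not converge", spec.response)
    return fit


def spec_columns(spec: ModelSpec) -> list:
    cols = []

    def walk(t):
        if isinstance(t, (F, N)):
            cols.append(t.col)
        else:
            walk(t.a)
            walk(t.b)
    for t in spec.fixed:
        walk(t)
    return cols


def isinstance_col(spec: ModelSpec, col: str) -> bool:
    """True if ``col`` enters the spec as a categorical factor."""
    found = []

    def walk(t):
        if isinstance(t, F) and t.col == col:
            found.append(True)
        elif isinstance(t, Ix):
            walk(t.a)
            walk(t.b)
    for t in spec.fixed:
        walk(t)
    return bool(found)


def select_random_structure(spec: ModelSpec, data: pd.DataFrame,
                            candidates: list) -> ModelFit:
    """Fit every candidate random structure, return the minimal-AIC fit.

    ``candidates`` is a list of (random, olre) pairs, e.g.
    ``[(("SS",), False), (("SS","SSB"), False), (("SS","SSB"), True)]``.
    Ties break toward fewer random terms (candidate order is preserved for
    determinism). Non-convergent candidates are skipped; all failing is an
    error.
    """
    fits = []
    for random, olre in candidates:
        try:
            fit = fit_mixed(spec, data, random=random, olre=olre)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            log.warning("candidate %s olre=%s failed: %s", random, olre, exc)
            continue
        if fit.converged:
            fits.append(fit)
    if not fits:
        raise ConvergenceError("no candidate random structure converged")
    n_terms = [len(f.random) + int(f.olre) for f in fits]
    aics = np.array([f.aic for f in fits])
    best = min(range(len(fits)),
               key=lambda i: (round(aics[i], 6), n_terms[i], i))
    return fits[best]


def gate_against_null(main: ModelFit, null: ModelFit) -> str:
    """'keep' unless the main model's AIC exceeds the null's ('discard').

    Equal AICs keep the main model (logged).
    """
    if main.spec.response != null.spec.response:
        raise ValueError("gate compares models of the same response")
    if main.aic > null.aic:
        return "discard"
    if main.aic == null.aic:
        log.info("gate_against_null: AIC tie for %s, keeping main",
                 main.spec.response)
    return "keep"


def check_overdispersion(fit: ModelFit) -> float:
    """Pearson ratio: squared scaled residuals over residual df.

    Without an observation-level random effect this is the standard
    conditional check, Σ((y−μ̂)/√μ̂)²/(n−k): near 1 for equidispersed
    counts, above 1 when extra-Poisson variation is unmodelled. With an
    OLRE the check marginalises over it — a log-normal observation
    intercept with variance σ² gives E[y] = μ·e^{σ²/2} and
    Var[y] = E[y] + E[y]²(e^{σ²}−1) — so a model whose OLRE has absorbed
    the overdispersion again shows a ratio near 1 (conditioning on the
    OLRE modes instead would over-shrink the residuals).
    """
    if fit.family != "poisson":
        raise ValueError("overdispersion check applies to poisson fits only")
    res = fit.result
    y = res.fitted + res.residuals
    if fit.olre and res.olre is not None:
        s2 = res.var_components.get("OLRE", 0.0)
        eta_no_olre = np.log(np.maximum(res.fitted, 1e-300)) - res.olre
        mean = np.exp(eta_no_olre + s2 / 2.0)
        var = mean + mean ** 2 * (np.exp(s2) - 1.0)
    else:
        mean = res.fitted
        var = np.maximum(res.fitted, 1e-12)
    rdf = res.n_obs - len(res.beta) - len(res.var_components)
    return float(np.sum((y - mean) ** 2 / var) / rdf)


def anova_terms(fit: ModelFit) -> pd.DataFrame:
    """Wald F statistic per fixed term (terms fitted separately).

    F = (Lβ)'(LVL')⁻¹(Lβ)/rank(L) with the coefficient covariance V from
    the fit; the denominator degrees of freedom are the residual count
    n − p (recorded in the output). Returns a frame with columns term,
    F, ndf, ddf, p.
    """
    labels = fit.design.labels
    beta = fit.result.beta
    V = fit.result.vcov
    ddf = fit.result.n_obs - len(beta)
    rows = []
    for term, term_labels in fit.design.term_labels().items():
        idx = [labels.index(l) for l in term_labels]
        if not idx:
            raise ValueError(f"term {term} has no estimable coefficients "
                             "(single-level factor or aliased)")
        L = np.zeros((len(idx), len(beta)))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        lb = L @ beta
        lvl = L @ V @ L.T
        try:
            fstat = float(lb @ np.linalg.solve(lvl, lb)) / len(idx)
        except np.linalg.LinAlgError:
            raise ValueError(f"aliased coefficients in term {term}")
        p = float(stats.f.sf(fstat, len(idx), ddf))
        rows.append((term, fstat, len(idx), ddf, p))
    return pd.DataFrame(rows, columns=["term", "F", "ndf", "ddf", "p"])
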