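"""Mixed-effects estimation engine.

Two fitters live here, both restricted to random *intercepts*, which is all
hierarchical ecological survey designs of the study/block/site kind require:

* :func:`fit_lmm` — Gaussian linear mixed model, exact maximum likelihood.
  The residual variance and fixed effects are profiled out analytically, so
  the numerical search runs only over the log variance *ratios* of the
  grouping factors (study, block-within-study).

* :func:`fit_glmm_poisson` — Poisson log-link GLMM via a Laplace
  approximation to the marginal likelihood (the same approximation class as
  lme4's ``glmer``).  An optional observation-level random effect (OLRE)
  absorbs extra-Poisson dispersion; it is handled analytically as a diagonal
  block so the cost stays O(n·q²) with q the number of group levels.

Both return a :class:`MixedResult` exposing ``beta``, ``vcov``, ``aic``,
``loglik``, variance components, conditional fitted values and residuals —
the contract every downstream stage (effect bootstrap, overdispersion check,
Moran screen) consumes.

All likelihood evaluations exploit the Woodbury identity: with U the
horizontally stacked group indicator matrices (n × q) and G the diagonal of
per-level variances, (I + U G Uᵀ)⁻¹ and its log-determinant reduce to a q × q
solve via M = G⁻¹ + UᵀU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

# Numerical policy: variance ratios are searched on the log scale within
# these bounds; a component pinned at the lower bound is reported as 0
# ("singular fit" warning), mirroring common mixed-model practice.
_LOG_VAR_LO = -12.0
_LOG_VAR_HI = 6.0
_SINGULAR_TOL = 1e-4

REL_TOL = 1e-6       # relative change convergence tolerance
MAX_ITER = 500


class ConvergenceError(RuntimeError):
    """Raised when the optimiser cannot produce a usable fit."""


@dataclass
class MixedResult:
    """Container for a fitted mixed model (the backend contract)."""

    beta: np.ndarray               # fixed-effect estimates
    vcov: np.ndarray               # var-cov matrix of beta
    loglik: float                  # maximised (approximate) marginal log-lik
    aic: float
    family: str                    # "gaussian" | "poisson"
    var_components: dict           # group name -> variance (response scale)
    resid_var: float | None        # gaussian residual variance, else None
    ranef: dict                    # group name -> BLUP/conditional-mode vector
    group_names: tuple             # order of grouping factors
    n_obs: int
    n_params: int                  # count entering the AIC penalty
    fitted: np.ndarray             # conditional fitted values (response scale)
    residuals: np.ndarray          # conditional response residuals
    converged: bool
    singular: bool = False
    olre: np.ndarray | None = None # OLRE conditional modes (poisson only)
    messages: list = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def pearson_residuals(self) -> np.ndarray:
        if self.family == "poisson":
            return self.residuals / np.sqrt(np.maximum(self.fitted, 1e-12))
        return self.residuals / np.sqrt(self.resid_var)


def _one_hot(codes: np.ndarray) -> tuple[np.ndarray, int]:
    """Dense n x q indicator matrix from integer group codes."""
    codes = np.asarray(codes)
    q = int(codes.max()) + 1 if codes.size else 0
    U = np.zeros((codes.size, q))
    U[np.arange(codes.size), codes] = 1.0
    return U, q


def _encode_groups(groups: dict) -> tuple[np.ndarray, list, list]:
    """Stack indicator matrices for every grouping factor.

    Returns (U, sizes, names) where sizes[k] is the number of levels of
    factor k and U has sum(sizes) columns in factor order.
    """
    mats, sizes, names = [], [], []
    for name, codes in groups.items():
        codes = np.asarray(codes)
        _, inv = np.unique(codes, return_inverse=True)
        U_k, q_k = _one_hot(inv)
        mats.append(U_k)
        sizes.append(q_k)
        names.append(name)
    return np.hstack(mats), sizes, names


def _expand(gammas: np.ndarray, sizes: list) -> np.ndarray:
    return np.repeat(gammas, sizes)


# ---------------------------------------------------------------------------
# Gaussian LMM (exact ML)
# ---------------------------------------------------------------------------

def fit_lmm(y, X, groups: dict) -> MixedResult:
    """Exact-ML Gaussian linear mixed model with random intercepts.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) fixed-effects design (first column usually the intercept).
    groups : mapping name -> (n,) array of group labels, one entry per
        random-intercept factor (e.g. study, block-within-study).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ConvergenceError("more fixed-effect columns than observations")
    U, sizes, names = _encode_groups(groups)
    K = len(sizes)

    # Sufficient cross-products: every likelihood evaluation is then O(q^3).
    UtU = U.T @ U
    UtX = U.T @ X
    Uty = U.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def profiled(theta):
        """Profiled -2 log-likelihood over log variance ratios theta.

        Returns (-2ll, beta, rssw, logdetW, Minv_chol info) for reuse.
        """
        g = _expand(np.exp(theta), sizes)
        M = UtU + np.diag(1.0 / g)
        cM, low = _chol(M)
        logdetW = 2.0 * np.sum(np.log(np.diag(cM))) + np.sum(np.log(g))
        # X' W^-1 X = XtX - UtX' M^-1 UtX  (and friends)
        MiUtX = _chol_solve(cM, UtX)
        MiUty = _chol_solve(cM, Uty)
        A = XtX - UtX.T @ MiUtX
        b = Xty - UtX.T @ MiUty
        yWy = yty - Uty @ MiUty
        beta = np.linalg.solve(A, b)
        rssw = max(yWy - b @ beta, 1e-300)
        sigma2 = rssw / n
        m2ll = n * (np.log(2 * np.pi * sigma2) + 1.0) + logdetW
        return m2ll, beta, rssw, logdetW, A

    def objective(theta):
        theta = np.clip(theta, _LOG_VAR_LO, _LOG_VAR_HI)
        try:
            return profiled(theta)[0]
        except np.linalg.LinAlgError:
            return np.inf

    x0 = np.full(K, np.log(0.25))
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-8,
                                     "maxiter": 200 * (K + 1) * MAX_ITER // 500})
    theta = np.clip(res.x, _LOG_VAR_LO, _LOG_VAR_HI)
    m2ll, beta, rssw, _, A = profiled(theta)

    sigma2_ml = rssw / n
    sigma2 = rssw / (n - p)           # bias-adjusted scale for Wald vcov
    vcov = sigma2 * np.linalg.inv(A)

    gam = np.exp(theta)
    singular = bool(np.any(gam <= np.exp(_LOG_VAR_LO) * (1 + _SINGULAR_TOL)))
    messages = []
    if singular:
        messages.append("singular fit: a random-effect variance is ~0")

    # BLUPs: u = G U' W^-1 r with r = y - X beta.
    g = _expand(gam, sizes)
    r = y - X @ beta
    M = UtU + np.diag(1.0 / g)
    Utr = U.T @ r
    u = g * (Utr - UtU @ np.linalg.solve(M, Utr))
    fitted = X @ beta + U @ u
    ranef, off = {}, 0
    for name, q_k in zip(names, sizes):
        ranef[name] = u[off:off + q_k]
        off += q_k

    var_components = {name: float(sigma2_ml * gk) for name, gk in zip(names, gam)}
    n_params = p + K + 1
    ll = -0.5 * m2ll
    return MixedResult(
        beta=beta, vcov=vcov, loglik=ll, aic=-2 * ll + 2 * n_params,
        family="gaussian", var_components=var_components,
        resid_var=float(sigma2_ml), ranef=ranef, group_names=tuple(names),
        n_obs=n, n_params=n_params, fitted=fitted, residuals=y - fitted,
        converged=bool(res.success or res.fun < np.inf), singular=singular,
        messages=messages,
    )


def _chol(M):
    c = np.linalg.cholesky(M)
    return c, True


def _chol_solve(c, B):
    z = np.linalg.solve(c, B)
    return np.linalg.solve(c.T, z)


# ---------------------------------------------------------------------------
# Poisson GLMM (Laplace)
# ---------------------------------------------------------------------------

def fit_glmm_poisson(y, X, groups: dict, olre: bool = False) -> MixedResult:
    """Laplace-approximate ML Poisson log-link GLMM with random intercepts.

    ``olre=True`` adds an observation-level random intercept (one level per
    observation) absorbing overdispersion; its diagonal structure is handled
    in closed form rather than through the generic indicator stack.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("poisson family requires non-negative integer response")
    U, sizes, names = _encode_groups(groups)
    q = U.shape[1]
    K = len(sizes) + (1 if olre else 0)
    C = np.hstack([X, U])                      # joint (beta, v) design
    lgam_y = special.gammaln(y + 1.0)

    # warm-start state shared across outer objective evaluations
    state = {"beta": None, "v": None, "o": None}

    def inner(theta):
        """Joint penalized Newton for (beta, v, o) at fixed variance ratios."""
        gam_v = _expand(np.exp(theta[:len(sizes)]), sizes)
        gam_o = float(np.exp(theta[-1])) if olre else 0.0
        if state["beta"] is None:
            eta0 = np.log(y + 0.5)
            beta = np.linalg.lstsq(X, eta0, rcond=None)[0]
            v = np.zeros(q)
            o = np.zeros(n)
        else:
            beta, v, o = state["beta"].copy(), state["v"].copy(), state["o"].copy()

        Pdiag = np.concatenate([np.zeros(p), 1.0 / gam_v])

        def penalized(beta, v, o):
            eta = np.clip(X @ beta + U @ v + o, -30, 30)
            mu = np.exp(eta)
            f = float(y @ eta - mu.sum() - lgam_y.sum()
                      - 0.5 * np.sum(v * v / gam_v)
                      - (0.5 * np.sum(o * o) / gam_o if olre else 0.0))
            return f, eta, mu

        f, eta, mu = penalized(beta, v, o)
        converged = False
        for _ in range(MAX_ITER):
            if olre:
                Wt = mu / (1.0 + gam_o * mu)           # Schur-reduced weights
                g_o = (y - mu) - o / gam_o
                shrink = gam_o * mu / (1.0 + gam_o * mu)
                g_c = C.T @ (y - mu) - Pdiag * np.concatenate([beta, v]) \
                    - C.T @ (shrink * g_o)
                H_cc = (C * Wt[:, None]).T @ C + np.diag(Pdiag)
                try:
                    delta_c = np.linalg.solve(H_cc, g_c)
                except np.linalg.LinAlgError:
                    return None
                delta_o = (g_o - mu * (C @ delta_c)) / (mu + 1.0 / gam_o)
            else:
                Wt = mu
                g_c = C.T @ (y - mu) - Pdiag * np.concatenate([beta, v])
                H_cc = (C * Wt[:, None]).T @ C + np.diag(Pdiag)
                try:
                    delta_c = np.linalg.solve(H_cc, g_c)
                except np.linalg.LinAlgError:
                    return None
                delta_o = 0.0

            step = 1.0
            for _ in range(30):
                nb = beta + step * delta_c[:p]
                nv = v + step * delta_c[p:]
                no = o + step * delta_o if olre else o
                nf, neta, nmu = penalized(nb, nv, no)
                if nf >= f - 1e-12:
                    break
                step *= 0.5
            improved = nf - f
            beta, v, o, eta, mu = nb, nv, (no if olre else o), neta, nmu
            prev_f, f = f, nf
            if abs(improved) < REL_TOL * (1.0 + abs(f)):
                converged = True
                break

        state.update(beta=beta, v=v, o=o)
        # Laplace log-likelihood at the joint mode.
        if olre:
            Wt = mu / (1.0 + gam_o * mu)
            logdet_D = np.sum(np.log(mu + 1.0 / gam_o))
        else:
            Wt = mu
            logdet_D = 0.0
        Hv = (U * Wt[:, None]).T @ U + np.diag(1.0 / gam_v)
        sign, logdet_Hv = np.linalg.slogdet(Hv)
        if sign <= 0:
            return None
        logdet_G = float(np.sum(np.log(gam_v))) + (n * np.log(gam_o) if olre else 0.0)
        ll = (float(y @ eta - mu.sum() - lgam_y.sum())
              - 0.5 * np.sum(v * v / gam_v)
              - (0.5 * np.sum(o * o) / gam_o if olre else 0.0)
              - 0.5 * logdet_G - 0.5 * (logdet_Hv + logdet_D)
              - 0.5 * 0.0)
        return ll, beta, v, o, mu, Wt, converged

    def objective(theta):
        theta = np.clip(theta, _LOG_VAR_LO, _LOG_VAR_HI)
        out = inner(theta)
        return np.inf if out is None else -out[0]

    x0 = np.full(K, np.log(0.2))
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-6,
                                     "maxiter": 400 * K})
    # restart from the first optimum: NM simplices over >2 variance
    # parameters occasionally collapse early
    res2 = optimize.minimize(objective, res.x, method="Nelder-Mead",
                             options={"xatol": 1e-5, "fatol": 1e-8,
                                      "maxiter": 400 * K})
    if res2.fun < res.fun:
        res = res2
    theta = np.clip(res.x, _LOG_VAR_LO, _LOG_VAR_HI)
    out = inner(theta)
    if out is None:
        raise ConvergenceError("poisson GLMM inner solve failed at optimum")
    ll, beta, v, o, mu, Wt, inner_ok = out

    # Wald vcov of beta: top-left block of the inverse joint Hessian after
    # eliminating the OLRE block.
    gam_v = _expand(np.exp(theta[:len(sizes)]), sizes)
    Pdiag = np.concatenate([np.zeros(p), 1.0 / gam_v])
    H_cc = (C * Wt[:, None]).T @ C + np.diag(Pdiag)
    vcov = np.linalg.inv(H_cc)[:p, :p]

    gam = np.exp(theta)
    singular = bool(np.any(gam <= np.exp(_LOG_VAR_LO) * (1 + _SINGULAR_TOL)))
    messages = []
    if singular:
        messages.append("singular fit: a random-effect variance is ~0")

    ranef, off = {}, 0
    for name, q_k in zip(names, sizes):
        ranef[name] = v[off:off + q_k]
        off += q_k
    var_components = {name: float(g) for name, g in zip(names, gam[:len(sizes)])}
    if olre:
        var_components["OLRE"] = float(gam[-1])

    n_params = p + K
    fitted = mu
    return MixedResult(
        beta=beta, vcov=vcov, loglik=float(ll), aic=-2 * float(ll) + 2 * n_params,
        family="poisson", var_components=var_components, resid_var=None,
        ranef=ranef, group_names=tuple(names), n_obs=n, n_params=n_params,
        fitted=fitted, residuals=y - fitted,
        converged=bool(inner_ok and (res.success or np.isfinite(res.fun))),
        singular=singular, olre=(o if olre else None), messages=messages,
    )
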