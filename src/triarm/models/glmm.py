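"""Random-intercept binomial models for repeated binary outcomes.

Post-baseline binary endpoints (anaemia, stunting, ...) are modelled at
months 3 and 12 jointly with a child-level random intercept. The primary
link is log, so treatment contrasts exponentiate to prevalence ratios; if
the log-link fit fails to converge or pins fitted probabilities at one,
the model is refit with a logit link and the contrasts become odds
ratios, with the reason logged on the result.

The marginal likelihood integrates the random intercept by adaptive
Gauss-Hermite quadrature (default 15 nodes): per child the integrand is
re-centred at its mode with a curvature-matched scale before applying
the Hermite rule. The baseline value of the same indicator enters as a
covariate — the shared-baseline trick used for continuous outcomes does
not transfer cleanly to a nonlinear link.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp
from numpy.polynomial.hermite_e import hermegauss

from .common import EffectEstimate, non_estimable, wald_effect

ACTIVE_ARMS = ("iron", "mnp")
_CLIP = -1e-10  # upper bound on log-probabilities for the log link


def _design(tab: pd.DataFrame, covariates, baseline: pd.Series | None):
    X = pd.DataFrame(index=tab.index)
    X["intercept"] = 1.0
    X["visit2"] = (tab["visit"] == 2).astype(float)
    for arm in ACTIVE_ARMS:
        X[arm] = (tab["arm"] == arm).astype(float)
        X[f"{arm}:visit2"] = X[arm] * X["visit2"]
    for col in ("union", "sex"):
        levels = sorted(tab[col].astype(str).unique())
        for lev in levels[1:]:
            X[f"{col}[{lev}]"] = (tab[col].astype(str) == lev).astype(float)
    for cov in covariates:
        X[cov] = pd.to_numeric(tab[cov]).astype(float)
    if baseline is not None:
        X["baseline"] = baseline.to_numpy(float)
    return X


def _obs_loglik(g: np.ndarray, y: np.ndarray, link: str) -> np.ndarray:
    """Per-observation log-likelihood at linear predictor g."""
    if link == "logit":
        return y * g - np.logaddexp(0.0, g)
    gc = np.minimum(g, _CLIP)
    return np.where(y == 1, gc, np.log1p(-np.exp(gc)))


def _obs_score(g, y, link):
    if link == "logit":
        return y - expit(g)
    gc = np.minimum(g, _CLIP)
    eg = np.exp(gc)
    return np.where(y == 1, 1.0, -eg / (1.0 - eg))


def _obs_curv(g, y, link):
    if link == "logit":
        mu = expit(g)
        return mu * (1.0 - mu)
    gc = np.minimum(g, _CLIP)
    eg = np.exp(gc)
    return np.where(y == 1, 0.0, eg / (1.0 - eg) ** 2)


def _find_modes(eta, y, cidx, n, tau2, link, iters=25):
    b = np.zeros(n)
    for _ in range(iters):
        g = eta + b[cidx]
        score = np.bincount(cidx, _obs_score(g, y, link), n) - b / tau2
        curv = np.bincount(cidx, _obs_curv(g, y, link), n) + 1.0 / tau2
        step = score / curv
        step = np.clip(step, -2.0, 2.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-9:
            break
    g = eta + b[cidx]
    curv = np.bincount(cidx, _obs_curv(g, y, link), n) + 1.0 / tau2
    return b, curv


def _marginal_loglik(beta, log_tau, X, y, cidx, n, link, nodes, weights):
    eta = X @ beta
    tau = np.exp(log_tau)
    tau2 = tau * tau
    if tau < 1e-8:
        return float(np.sum(_obs_loglik(eta, y, link)))
    bhat, curv = _find_modes(eta, y, cidx, n, tau2, link)
    scale = 1.0 / np.sqrt(curv)
    # adaptive rule: b = bhat + scale * node
    vals = np.empty((len(nodes), n))
    for k, (x, w) in enumerate(zip(nodes, weights)):
        b = bhat + scale * x
        g = eta + b[cidx]
        lp = np.bincount(cidx, _obs_loglik(g, y, link), n)
        lp += -0.5 * b * b / tau2 - 0.5 * np.log(2.0 * np.pi * tau2)
        vals[k] = lp + 0.5 * x * x + np.log(w) + np.log(scale)
    return float(np.sum(logsumexp(vals, axis=0)))


@dataclass
class BinaryMixedFit:
    beta: pd.Series
    cov_beta: pd.DataFrame
    tau: float
    link: str
    loglik: float
    converged: bool
    n_children: int
    fallback_reason: str | None = None
    messages: list = field(default_factory=list)

    @property
    def ratio_label(self) -> str:
        return "prevalence ratio" if self.link == "log" else "odds ratio"


def _fit_glm(y, X, n, link):
    """Degenerate case tau = 0: ordinary binomial GLM."""
    import statsmodels.api as sm
    import warnings
    sm_link = (sm.families.links.Log() if link == "log"
               else sm.families.links.Logit())
    start = np.zeros(X.shape[1])
    p0 = np.clip(y.mean(), 1e-4, 1 - 1e-4)
    start[0] = np.log(p0) if link == "log" else np.log(p0 / (1 - p0))
    boundary = False
    try:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial(link=sm_link)
                         ).fit(start_params=start, maxiter=200)
            ll_val = float(res.llf)
        converged = bool(res.converged)
        if link == "log" and np.any(np.asarray(res.mu) >= 1.0 - 1e-10):
            boundary, converged = True, False
        beta = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        ll = ll_val
    except Exception:
        converged = False
        beta = start
        cov = np.full((X.shape[1],) * 2, np.nan)
        ll = float("nan")
    fit = BinaryMixedFit(
        beta=pd.Series(beta, index=X.columns),
        cov_beta=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        tau=0.0, link=link, loglik=ll, converged=converged, n_children=n)
    if boundary:
        fit.messages.append("log-link fit reached the probability boundary")
    return fit


def _fit_link(tab, y, X, cidx, n, link, var_fixed, n_quad):
    if var_fixed is not None and var_fixed == 0:
        return _fit_glm(y, X.astype(float), n, link)
    nodes, weights = hermegauss(n_quad)
    weights = weights / np.sqrt(2.0 * np.pi)  # probabilists' normalisation
    Xmat = X.to_numpy(float)
    p = Xmat.shape[1]

    free_tau = var_fixed is None

    def unpack(theta):
        beta = theta[:p]
        log_tau = theta[p] if free_tau else (
            0.5 * np.log(var_fixed) if var_fixed > 0 else -np.inf)
        return beta, log_tau

    def nll(theta):
        beta, log_tau = unpack(theta)
        ll = _marginal_loglik(beta, log_tau, Xmat, y, cidx, n, link,
                              nodes, weights)
        return -ll if np.isfinite(ll) else 1e10

    # start from pooled GLM-ish values
    p0 = np.clip(y.mean(), 1e-3, 1 - 1e-3)
    beta0 = np.zeros(p)
    beta0[0] = np.log(p0) if link == "log" else np.log(p0 / (1 - p0))
    theta0 = np.concatenate([beta0, [np.log(0.5)]]) if free_tau else beta0
    res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                            options={"maxiter": 500, "gtol": 1e-6})
    beta, log_tau = unpack(res.x)
    tau = float(np.exp(log_tau)) if np.isfinite(log_tau) else 0.0

    # observed-information covariance for beta via numerical Hessian
    eps = 1e-4
    k = len(res.x)
    H = np.zeros((k, k))
    f0 = nll(res.x)
    grads = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            fpp = nll(res.x + ei + ej)
            fpm = nll(res.x + ei - ej)
            fmp = nll(res.x - ei + ej)
            fmm = nll(res.x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    try:
        cov = np.linalg.inv(H)[:p, :p]
        ok_cov = np.all(np.diag(cov) > 0)
    except np.linalg.LinAlgError:
        cov, ok_cov = np.full((p, p), np.nan), False

    # boundary check for the log link: fitted probabilities at b = 0
    boundary = False
    if link == "log":
        boundary = bool(np.max(Xmat @ beta) > -1e-8)
    converged = bool(res.success) and ok_cov and not boundary
    fit = BinaryMixedFit(
        beta=pd.Series(beta, index=X.columns),
        cov_beta=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        tau=tau, link=link, loglik=float(-f0), converged=converged,
        n_children=n,
    )
    if boundary:
        fit.messages.append("log-link fit reached the probability boundary")
    elif not res.success:
        fit.messages.append(f"optimizer: {res.message}")
    return fit


def fit_binary_mixed(tab: pd.DataFrame, outcome: str, link: str = "log",
                     covariates=(), var_fixed: float | None = None,
                     n_quad: int = 15, include_baseline: bool = True):
    """Fit the random-intercept binomial model for a repeated binary
    outcome at months 3 and 12.

    Returns a :class:`BinaryMixedFit`; if the requested log link fails
    (non-convergence or fitted probabilities at 1) the logit fallback is
    fitted automatically and ``fallback_reason`` records why.
    """
    post = tab[tab["visit"].isin([1, 2])].copy()
    y_all = pd.to_numeric(post[outcome], errors="coerce")
    post = post[y_all.notna()]
    y = y_all.dropna().to_numpy(float)
    levels = np.unique(y)
    if len(levels) < 2:
        raise ValueError(
            f"outcome {outcome!r} has a single observed level; the model "
            f"is not estimable")
    if not set(levels) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} is not binary")

    baseline = None
    if include_baseline:
        base = tab[tab["visit"] == 0].set_index("child_id")[outcome]
        baseline = post["child_id"].map(base).fillna(base.mean())
    X = _design(post, covariates, baseline)
    X = X.loc[:, (X != 0).any(axis=0)]  # arms/visits absent from the data
    child_ids, cidx = np.unique(post["child_id"].to_numpy(), return_inverse=True)
    n = len(child_ids)

    fit = _fit_link(post, y, X, cidx, n, link, var_fixed, n_quad)
    if link == "log" and not fit.converged:
        reason = "; ".join(fit.messages) or "log-link non-convergence"
        fit = _fit_link(post, y, X, cidx, n, "logit", var_fixed, n_quad)
        fit.fallback_reason = reason
        fit.messages.append("fell back to logit link: " + reason)
    return fit


def binary_effects(fit: BinaryMixedFit, ci_level: float = 0.95):
    """Exponentiated treatment contrasts per comparison and visit."""
    cols = list(fit.beta.index)
    out = []
    for comparison in (("iron", "placebo"), ("mnp", "placebo"),
                       ("iron", "mnp")):
        for visit in (1, 2):
            c = np.zeros(len(cols))
            missing_term = False
            for arm, sign in zip(comparison, (1.0, -1.0)):
                if arm == "placebo":
                    continue
                if arm not in cols:
                    missing_term = True
                    break
                c[cols.index(arm)] += sign
                if visit == 2 and f"{arm}:visit2" in cols:
                    c[cols.index(f"{arm}:visit2")] += sign
            if missing_term:
                out.append(non_estimable(comparison, visit, ci_level,
                                         label=fit.ratio_label))
                continue
            est = float(c @ fit.beta.to_numpy())
            se = float(np.sqrt(c @ fit.cov_beta.to_numpy() @ c))
            if not np.isfinite(se):
                out.append(non_estimable(comparison, visit, ci_level,
                                         label=fit.ratio_label))
                continue
            out.append(wald_effect(comparison, visit, est, se, ci_level,
                                   log_scale=True, label=fit.ratio_label))
    return out
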