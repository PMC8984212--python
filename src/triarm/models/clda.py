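"""Constrained longitudinal data analysis (cLDA).

A multivariate-normal model for an outcome measured at baseline and two
follow-up visits in a randomised trial. The mean model treats visit as
categorical and includes treatment-by-visit interactions but *no*
treatment main effect: all arms share the baseline mean, which is
justified by randomisation and recovers efficiency relative to ANCOVA
while using every child with at least one observed visit. Treatment
effects are the interaction coefficients — differences in mean change
from baseline versus placebo at each follow-up visit.

Estimation maximises the observed-data likelihood: each child contributes
the marginal normal likelihood of its observed sub-vector, which is valid
under missing-at-random dropout. The 3x3 within-child covariance is
profiled out — for a candidate covariance the mean coefficients solve
generalised least squares in closed form — and the covariance parameters
(log-Cholesky for unstructured; variance plus correlation transforms for
AR(1), Toeplitz and compound symmetry) are optimised by quasi-Newton.
On non-convergence the structures are tried in the order unstructured,
AR(1), Toeplitz, compound symmetry; the first converged fit wins and is
labelled.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ..config import ARMS
from .common import EffectEstimate, wald_effect

N_VISITS = 3
STRUCTURES = ("unstructured", "ar1", "toeplitz", "cs")
ACTIVE_ARMS = ("iron", "mnp")  # placebo is the reference


# ------------------------------------------------------------------ design
def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    levels = sorted(pd.unique(series.dropna().astype(str)))
    return pd.DataFrame(
        {f"{prefix}[{lev}]": (series.astype(str) == lev).astype(float)
         for lev in levels[1:]}, index=series.index)


def build_design(tab: pd.DataFrame, covariates=(), subgroup: str | None = None):
    """Model matrix for the constrained mean model.

    Columns: intercept; visit indicators; treatment-by-visit effects for
    the active arms (zero at baseline by construction — the cLDA
    constraint); drop-first dummies for union and sex; extra covariates
    (numeric as-is, non-numeric as drop-first dummies); and, when
    ``subgroup`` is given, subgroup main effect, subgroup-by-visit and
    subgroup-by-treatment-by-visit interactions.
    """
    X = pd.DataFrame(index=tab.index)
    X["intercept"] = 1.0
    for t in (1, 2):
        X[f"visit{t}"] = (tab["visit"] == t).astype(float)
    for arm in ACTIVE_ARMS:
        is_arm = (tab["arm"] == arm).astype(float)
        for t in (1, 2):
            X[f"{arm}:visit{t}"] = is_arm * X[f"visit{t}"]
    for col, pref in (("union", "union"), ("sex", "sex")):
        X = pd.concat([X, _dummies(tab[col], pref)],
                      axis=1)
    for cov in covariates:
        if cov not in tab.columns:
            raise ValueError(f"covariate {cov!r} absent from the data")
        s = tab[cov]
        if pd.api.types.is_numeric_dtype(s):
            X[cov] = s.astype(float)
        else:
            X = pd.concat([X, _dummies(s, cov)], axis=1)
            # rater-style covariates also interact with visit per the
            # sensitivity models; caller opts in via subgroup-free extras
    if subgroup is not None:
        g = _dummies(tab[subgroup], f"sub({subgroup})")
        for col in g.columns:
            if subgroup not in ("union", "sex"):
                # stratification factors already carry a main effect
                X[col] = g[col]
            for t in (1, 2):
                X[f"{col}:visit{t}"] = g[col] * X[f"visit{t}"]
            for arm in ACTIVE_ARMS:
                for t in (1, 2):
                    X[f"{col}:{arm}:visit{t}"] = g[col] * X[f"{arm}:visit{t}"]
    return X


def interaction_columns(X: pd.DataFrame, subgroup: str) -> list:
    """Names of the subgroup-by-treatment-by-visit columns."""
    pre = f"sub({subgroup})"
    return [c for c in X.columns
            if c.startswith(pre) and any(f":{a}:" in c for a in ACTIVE_ARMS)]


def _check_full_rank(X: pd.DataFrame):
    mat = X.to_numpy(float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name one offending column: the first whose removal restores rank
        for j, name in enumerate(X.columns):
            sub = np.delete(mat, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(
                    f"model matrix is singular; column {name!r} is "
                    f"collinear with the others")
        raise ValueError("model matrix is singular")


# -------------------------------------------------------------- covariance
def _theta0(structure: str, sigma0: np.ndarray) -> np.ndarray:
    sd = float(np.sqrt(np.mean(np.diag(sigma0))))
    off = sigma0[np.triu_indices(N_VISITS, 1)]
    rho = float(np.clip(np.mean(off) / sd**2, -0.4, 0.9))
    if structure == "unstructured":
        try:
            L = np.linalg.cholesky(sigma0)
        except np.linalg.LinAlgError:
            L = np.diag(np.sqrt(np.clip(np.diag(sigma0), 1e-6, None)))
        return np.array([np.log(L[0, 0]), np.log(L[1, 1]), np.log(L[2, 2]),
                         L[1, 0], L[2, 0], L[2, 1]])
    if structure in ("ar1", "cs"):
        return np.array([np.log(sd), np.arctanh(np.clip(rho, -0.49, 0.95))])
    if structure == "toeplitz":
        z = np.arctanh(np.clip(rho, -0.45, 0.9))
        return np.array([np.log(sd), z, z * 0.8])
    raise ValueError(f"unknown covariance structure {structure!r}")


def build_sigma(theta: np.ndarray, structure: str) -> np.ndarray:
    """Map an unconstrained parameter vector to a 3x3 covariance."""
    return _sigma_and_jac(theta, structure, want_jac=False)[0]


def _sigma_and_jac(theta: np.ndarray, structure: str, want_jac: bool = True):
    """Covariance matrix and its derivatives w.r.t. each parameter."""
    idx = np.abs(np.subtract.outer(np.arange(3), np.arange(3)))
    if structure == "unstructured":
        L = np.zeros((3, 3))
        L[0, 0], L[1, 1], L[2, 2] = np.exp(theta[:3])
        L[1, 0], L[2, 0], L[2, 1] = theta[3:]
        sigma = L @ L.T
        if not want_jac:
            return sigma, None
        jac = []
        positions = [(0, 0), (1, 1), (2, 2), (1, 0), (2, 0), (2, 1)]
        for j, (r, c) in enumerate(positions):
            dL = np.zeros((3, 3))
            dL[r, c] = L[r, c] if j < 3 else 1.0  # chain rule for exp(diag)
            jac.append(dL @ L.T + L @ dL.T)
        return sigma, jac
    sd2 = np.exp(2.0 * theta[0])
    if structure == "ar1":
        rho = np.tanh(theta[1])
        sigma = sd2 * rho ** idx
        if not want_jac:
            return sigma, None
        with np.errstate(divide="ignore", invalid="ignore"):
            dcorr = np.where(idx == 0, 0.0,
                             idx * np.where(rho == 0.0,
                                            np.where(idx == 1, 1.0, 0.0),
                                            rho ** (idx - 1)))
        return sigma, [2.0 * sigma, sd2 * dcorr * (1.0 - rho ** 2)]
    if structure == "cs":
        # compound symmetry is positive-definite for rho in (-1/2, 1)
        s = 1.0 / (1.0 + np.exp(-theta[1]))
        rho = -0.5 + 1.5 * s
        sigma = sd2 * np.where(idx == 0, 1.0, rho)
        if not want_jac:
            return sigma, None
        dcorr = np.where(idx == 0, 0.0, 1.0) * 1.5 * s * (1.0 - s)
        return sigma, [2.0 * sigma, sd2 * dcorr]
    if structure == "toeplitz":
        r1, r2 = np.tanh(theta[1]), np.tanh(theta[2])
        corr = np.array([[1, r1, r2], [r1, 1, r1], [r2, r1, 1.0]])
        sigma = sd2 * corr
        if not want_jac:
            return sigma, None
        d1 = sd2 * (idx == 1).astype(float) * (1.0 - r1 ** 2)
        d2 = sd2 * (idx == 2).astype(float) * (1.0 - r2 ** 2)
        return sigma, [2.0 * sigma, d1, d2]
    raise ValueError(f"unknown covariance structure {structure!r}")


# ---------------------------------------------------------------- fitting
@dataclass
class CldaFit:
    """Fitted constrained longitudinal model."""
    beta: pd.Series
    cov_beta: pd.DataFrame
    sigma: np.ndarray
    structure: str
    loglik: float
    converged: bool
    n_children: int
    n_observations: int
    transform: str = "identity"
    outcome: str = ""
    subgroup: str | None = None
    interaction_test: dict | None = None
    messages: list = field(default_factory=list)

    def contrast(self, c: np.ndarray):
        est = float(c @ self.beta.to_numpy())
        se = float(np.sqrt(c @ self.cov_beta.to_numpy() @ c))
        return est, se

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "structure": self.structure,
            "transform": self.transform, "loglik": self.loglik,
            "converged": self.converged, "n_children": self.n_children,
            "n_observations": self.n_observations,
            "beta": self.beta.to_dict(),
            "sigma": self.sigma.tolist(),
            "interaction_test": self.interaction_test,
            "messages": self.messages,
        }


def _group_patterns(tab: pd.DataFrame, X: pd.DataFrame, y: np.ndarray):
    """Stack children into per-missingness-pattern arrays.

    Returns a list of (Y, Xs) with Y of shape (n, k) and Xs of shape
    (n, k, p) per observed-visit pattern, plus the child count.
    """
    p = X.shape[1]
    if not np.any(~np.isnan(y)):
        raise ValueError("no observed outcome values")
    frame = pd.DataFrame({
        "child_id": tab["child_id"].to_numpy(),
        "visit": tab["visit"].to_numpy(),
        "y": y, "_row": np.arange(len(tab), dtype=float),
    })
    wide_y = frame.pivot(index="child_id", columns="visit", values="y")
    wide_r = frame.pivot(index="child_id", columns="visit", values="_row")
    wide_y = wide_y.reindex(columns=[0, 1, 2]).to_numpy()
    wide_r = wide_r.reindex(columns=[0, 1, 2]).to_numpy()
    obs = ~np.isnan(wide_y)
    codes = obs @ np.array([1, 2, 4])
    Xmat = np.ascontiguousarray(X.to_numpy(float))
    out = []
    n_children = 0
    for code in np.unique(codes):
        if code == 0:
            continue  # child with no observed visit contributes nothing
        visits = np.flatnonzero([code & 1, code & 2, code & 4])
        sel = codes == code
        n_children += int(sel.sum())
        Y = wide_y[np.ix_(sel, visits)]
        rows = wide_r[np.ix_(sel, visits)].astype(int)
        Xs = Xmat[rows.ravel()].reshape(rows.shape + (p,))
        # sufficient statistics: the profile likelihood needs only these
        # cross-products, so each covariance evaluation is O(k^2 p^2)
        XX = np.einsum("nka,nlb->klab", Xs, Xs, optimize=True)
        XY = np.einsum("nka,nl->kla", Xs, Y, optimize=True)
        YY = np.einsum("nk,nl->kl", Y, Y)
        out.append((visits, Y.shape[0], XX, XY, YY))
    return out, n_children


def _profile_nll(sigma: np.ndarray, patterns, reml: bool,
                 dsigmas=None):
    """Negative observed-data log-likelihood with the mean profiled out.

    Returns (nll, beta_hat, A, grad) where A = sum_i X_i' W_i X_i and
    ``grad`` (present when ``dsigmas`` is given) is the analytic gradient
    w.r.t. the covariance parameters — by the envelope theorem the
    profiled mean drops out of the derivative.
    """
    p = patterns[0][2].shape[2]  # XX has shape (k, k, p, p)
    A = np.zeros((p, p))
    b = np.zeros(p)
    quad_y = 0.0
    logdet = 0.0
    n_obs = 0
    Ws = []
    for visits, n, XX, XY, YY in patterns:
        S = sigma[np.ix_(visits, visits)]
        sign, ld = np.linalg.slogdet(S)
        if sign <= 0:
            return np.inf, None, None, None
        W = np.linalg.inv(S)
        Ws.append(W)
        k = len(visits)
        n_obs += n * k
        logdet += n * ld
        A += np.tensordot(W, XX, axes=([0, 1], [0, 1]))
        b += np.tensordot(W, XY, axes=([0, 1], [0, 1]))
        quad_y += float(np.sum(W * YY))
    try:
        cA = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    beta = np.linalg.solve(A, b)
    quad = quad_y - float(beta @ b)
    nll = 0.5 * (n_obs * np.log(2.0 * np.pi) + logdet + quad)
    if reml:
        nll += float(np.sum(np.log(np.diag(cA))))
    if dsigmas is None:
        return nll, beta, A, None

    npar = len(dsigmas)
    grad = np.zeros(npar)
    dAs = [np.zeros((p, p)) for _ in range(npar)] if reml else None
    for (visits, n, XX, XY, YY), W in zip(patterns, Ws):
        # residual cross-products at the profiled mean
        Bb = np.tensordot(XY, beta, axes=([2], [0]))      # (k, k)
        Cb = np.einsum("klab,a,b->kl", XX, beta, beta, optimize=True)
        Roo = YY - Bb - Bb.T + Cb
        WRW = W @ Roo @ W
        for j, dS_full in enumerate(dsigmas):
            dS = dS_full[np.ix_(visits, visits)]
            grad[j] += 0.5 * (n * float(np.sum(W * dS))
                              - float(np.sum(WRW * dS)))
            if reml:
                dW = -W @ dS @ W
                dAs[j] += np.tensordot(dW, XX, axes=([0, 1], [0, 1]))
    if reml:
        Ainv = np.linalg.inv(A)
        for j in range(npar):
            grad[j] += 0.5 * float(np.sum(Ainv * dAs[j].T))
    return nll, beta, A, grad


def _pairwise_sigma(tab, y) -> np.ndarray:
    wide = pd.DataFrame({
        "child_id": tab["child_id"], "visit": tab["visit"], "y": y,
    }).pivot_table(index="child_id", columns="visit", values="y")
    wide = wide.reindex(columns=[0, 1, 2])
    S = wide.cov(min_periods=2).to_numpy()
    if np.isnan(S).any():
        v = np.nanvar(y)
        S = np.where(np.isnan(S), 0.0, S)
        np.fill_diagonal(S, np.where(np.diag(S) == 0, v, np.diag(S)))
    # nudge to positive definiteness
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 1e-4 * max(w.max(), 1.0), None)
    return V @ np.diag(w) @ V.T


def _fit_one_structure(structure, patterns, sigma0, reml, fixed_covariance):
    if fixed_covariance is not None:
        sigma = np.asarray(fixed_covariance, float)
        nll, beta, A, _ = _profile_nll(sigma, patterns, reml)
        return sigma, beta, A, -nll, True, None
    theta0 = _theta0(structure, sigma0)

    def objective(theta):
        sigma, dsigmas = _sigma_and_jac(theta, structure)
        nll, _, _, grad = _profile_nll(sigma, patterns, reml, dsigmas)
        if not np.isfinite(nll):
            return 1e12, np.zeros_like(theta)
        return nll, grad

    res = optimize.minimize(objective, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-14,
                                     "gtol": 1e-9})
    sigma = build_sigma(res.x, structure)
    nll, beta, A, _ = _profile_nll(sigma, patterns, reml)
    grad_norm = float(np.max(np.abs(np.atleast_1d(res.jac))))
    converged = np.isfinite(nll) and (bool(res.success) or grad_norm < 1e-4)
    return sigma, beta, A, -nll, converged, res


def fit_clda(tab: pd.DataFrame, outcome: str, covariance: str = "unstructured",
             covariates=(), transform: str = "identity",
             fixed_covariance=None, reml: bool = False,
             subgroup: str | None = None, fallback: bool = True) -> CldaFit:
    """Fit the constrained longitudinal model by observed-data ML.

    Parameters
    ----------
    tab : child-visit table (one row per child-visit) carrying ``outcome``,
        ``child_id``, ``visit``, ``arm``, ``union``, ``sex`` and any
        requested covariates. Rows with a missing outcome are dropped; a
        child contributes whichever visits it has.
    covariance : starting structure; with ``fallback`` the cascade
        unstructured -> AR(1) -> Toeplitz -> compound symmetry is walked on
        non-convergence and the winning structure is recorded.
    transform : "identity" or "log" (outcome logged before fitting; effect
        estimates are then exponentiated to ratios).
    fixed_covariance : hold the within-child covariance fixed at the given
        3x3 matrix and only estimate mean parameters (GLS).
    """
    y = pd.to_numeric(tab[outcome], errors="coerce").to_numpy(float)
    if transform == "log":
        with np.errstate(invalid="ignore"):
            y = np.log(y)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    observed_visits = set(tab.loc[~np.isnan(y), "visit"].unique())
    if len(observed_visits) < 2:
        raise ValueError("need observations at two or more visits")

    X = build_design(tab, covariates=covariates, subgroup=subgroup)
    keep = ~np.isnan(y)
    # terms never observed (e.g. visit-2 columns in two-visit data) drop out
    nonzero = (X.loc[keep] != 0).any(axis=0)
    X = X.loc[:, nonzero]
    _check_full_rank(X.loc[keep])
    patterns, n_children = _group_patterns(tab, X, y)
    sigma0 = _pairwise_sigma(tab, y)

    order = [covariance] + [s for s in STRUCTURES if s != covariance]
    if not fallback or fixed_covariance is not None:
        order = [covariance]
    messages = []
    chosen = None
    for structure in order:
        sigma, beta, A, ll, converged, res = _fit_one_structure(
            structure, patterns, sigma0, reml, fixed_covariance)
        if converged and beta is not None:
            chosen = (structure, sigma, beta, A, ll)
            break
        messages.append(f"{structure}: non-convergence, trying next "
                        f"structure")
    if chosen is None:
        raise RuntimeError(
            "constrained longitudinal fit failed to converge under every "
            "covariance structure")
    structure, sigma, beta, A, ll = chosen
    cov_beta = np.linalg.inv(A)
    n_obs = sum(n * len(visits) for visits, n, *_ in patterns)
    fit = CldaFit(
        beta=pd.Series(beta, index=X.columns),
        cov_beta=pd.DataFrame(cov_beta, index=X.columns, columns=X.columns),
        sigma=sigma, structure=structure, loglik=float(ll),
        converged=True, n_children=n_children, n_observations=n_obs,
        transform=transform, outcome=outcome, subgroup=subgroup,
        messages=messages,
    )
    if subgroup is not None:
        fit.interaction_test = _interaction_wald(fit, X, subgroup)
    return fit


def _interaction_wald(fit: CldaFit, X: pd.DataFrame, subgroup: str) -> dict:
    cols = interaction_columns(X, subgroup)
    idx = [list(X.columns).index(c) for c in cols]
    b = fit.beta.to_numpy()[idx]
    V = fit.cov_beta.to_numpy()[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    return {"statistic": stat, "df": df,
            "p_value": float(stats.chi2.sf(stat, df)), "columns": cols}


# ------------------------------------------------------------------ effects
def _effect_contrast(fit: CldaFit, comparison, visit: int) -> np.ndarray:
    cols = list(fit.beta.index)
    c = np.zeros(len(cols))
    for arm, sign in zip(comparison, (1.0, -1.0)):
        if arm == "placebo":
            continue
        name = f"{arm}:visit{visit}"
        if arm not in ARMS or name not in cols:
            raise ValueError(f"unknown arm or visit in comparison "
                             f"{comparison} at visit {visit}")
        c[cols.index(name)] = sign
    if visit not in (1, 2):
        raise ValueError("treatment effects exist at visits 1 and 2 only")
    return c


def estimate_effect(fit: CldaFit, comparison=("iron", "placebo"),
                    visit: int = 1, ci_level: float = 0.95) -> EffectEstimate:
    """Treatment effect as difference in mean change from baseline.

    For log-transformed outcomes the difference of log-means is
    exponentiated into a geometric-mean ratio.
    """
    if not fit.converged:
        raise ValueError("cannot form effects from a non-converged fit")
    c = _effect_contrast(fit, comparison, visit)
    est, se = fit.contrast(c)
    return wald_effect(comparison, visit, est, se, ci_level,
                       log_scale=(fit.transform == "log"),
                       label="geometric-mean ratio"
                       if fit.transform == "log" else "mean difference")


def subgroup_effects(fit: CldaFit, ci_level: float = 0.95) -> pd.DataFrame:
    """Per-subgroup-level effect rows for forest display.

    One row per comparison x visit x subgroup level, with Wald CIs from
    the extended fit.
    """
    if fit.subgroup is None:
        raise ValueError("fit has no subgroup terms")
    import re
    pre = f"sub({fit.subgroup})"
    cols = list(fit.beta.index)
    pat = re.compile(re.escape(pre) + r"\[(.+?)\]:(?:iron|mnp):visit[12]$")
    levels = sorted({m.group(1) for c in cols
                     for m in [pat.match(c)] if m})
    rows = []
    comparisons = [("iron", "placebo"), ("mnp", "placebo"), ("iron", "mnp")]
    for comparison in comparisons:
        for visit in (1, 2):
            base = _effect_contrast(fit, comparison, visit)
            for level in [None] + levels:
                c = base.copy()
                if level is not None:
                    for arm, sign in zip(comparison, (1.0, -1.0)):
                        if arm == "placebo":
                            continue
                        name = f"{pre}[{level}]:{arm}:visit{visit}"
                        c[cols.index(name)] = sign
                est, se = fit.contrast(c)
                eff = wald_effect(comparison, visit, est, se, ci_level,
                                  log_scale=(fit.transform == "log"))
                rows.append({"level": level if level is not None
                             else "reference", **eff.to_dict()})
    return pd.DataFrame(rows)
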