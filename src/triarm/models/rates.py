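"""Safety models: Poisson incidence-rate ratios and log-binomial risk
ratios.

Both are ordinary GLMs fitted through statsmodels. The Poisson model uses
log person-time as offset, so exponentiated treatment coefficients are
incidence-rate ratios. The log-binomial model estimates risk ratios
directly; when its constrained ML fit fails at the boundary (fitted
probabilities at 1) the documented fallback is a Poisson working model
with a robust (HC1 sandwich) variance, labelled as such.
"""
from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


from .common import EffectEstimate, non_estimable, wald_effect

ACTIVE_ARMS = ("iron", "mnp")
COMPARISONS = (("iron", "placebo"), ("mnp", "placebo"), ("iron", "mnp"))


@contextmanager
def _quiet():
    # the log-link binomial family intentionally violates its domain; the
    # boundary handling below deals with the consequences
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        yield


def _design(tab: pd.DataFrame, covariates) -> pd.DataFrame:
    X = pd.DataFrame(index=tab.index)
    X["intercept"] = 1.0
    for arm in ACTIVE_ARMS:
        X[arm] = (tab["arm"] == arm).astype(float)
    for col in covariates:
        s = tab[col]
        if pd.api.types.is_numeric_dtype(s):
            X[col] = s.astype(float)
        else:
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:
                X[f"{col}[{lev}]"] = (s.astype(str) == lev).astype(float)
    return X


@dataclass
class RateFit:
    beta: pd.Series
    cov_beta: pd.DataFrame
    model: str                      # 'poisson-irr', 'log-binomial', ...
    converged: bool
    fallback_reason: str | None = None
    messages: list = field(default_factory=list)


def _arm_contrast(cols, comparison):
    c = np.zeros(len(cols))
    for arm, sign in zip(comparison, (1.0, -1.0)):
        if arm != "placebo":
            c[cols.index(arm)] += sign
    return c


def _effects(fit: RateFit, tab, outcome_by_arm, ci_level, label):
    out = []
    cols = list(fit.beta.index)
    for comparison in COMPARISONS:
        # a comparison with zero events on both sides is non-estimable
        if all(outcome_by_arm.get(a, 0) == 0 for a in comparison):
            out.append(non_estimable(comparison, None, ci_level, label=label))
            continue
        c = _arm_contrast(cols, comparison)
        est = float(c @ fit.beta.to_numpy())
        se = float(np.sqrt(c @ fit.cov_beta.to_numpy() @ c))
        if not np.isfinite(se) or se > 50:
            out.append(non_estimable(comparison, None, ci_level, label=label))
            continue
        out.append(wald_effect(comparison, None, est, se, ci_level,
                               log_scale=True, label=label))
    return out


def fit_poisson_rate(tab: pd.DataFrame, counts: str, exposure: str,
                     covariates=(), ci_level: float = 0.95):
    """Incidence-rate ratios from a Poisson GLM with log-exposure offset.

    ``tab`` has one row per child with the event count, the person-time
    (in days, or any consistent unit) and the arm. Children with zero
    exposure are excluded. Returns (RateFit, list of EffectEstimate).
    """
    tab = tab[pd.to_numeric(tab[exposure], errors="coerce") > 0].copy()
    y = pd.to_numeric(tab[counts]).to_numpy(float)
    X = _design(tab, covariates)
    offset = np.log(pd.to_numeric(tab[exposure]).to_numpy(float))
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit()
    fit = RateFit(
        beta=pd.Series(res.params, index=X.columns),
        cov_beta=pd.DataFrame(res.cov_params(), index=X.columns,
                              columns=X.columns),
        model="poisson-irr", converged=bool(res.converged),
    )
    totals = tab.groupby("arm")[counts].sum().to_dict()
    return fit, _effects(fit, tab, totals, ci_level, "incidence rate ratio")


def fit_log_binomial(tab: pd.DataFrame, indicator: str, covariates=(),
                     ci_level: float = 0.95):
    """Risk ratios from a log-binomial GLM on a per-child binary indicator.

    On boundary non-convergence of the log-binomial likelihood the model
    falls back to a Poisson working model with HC1 sandwich variance
    (still estimating log risk ratios), and the effects are labelled
    accordingly.
    """
    tab = tab[pd.to_numeric(tab[indicator], errors="coerce").notna()].copy()
    y = pd.to_numeric(tab[indicator]).to_numpy(float)
    X = _design(tab, covariates)
    totals = tab.groupby("arm")[indicator].sum().to_dict()

    p0 = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    start = np.zeros(X.shape[1])
    start[0] = np.log(p0)
    fallback_reason = None
    try:
        with _quiet():
            model = sm.GLM(y, X, family=sm.families.Binomial(
                link=sm.families.links.Log()))
            res = model.fit(start_params=start, maxiter=200)
            mu = np.asarray(res.mu)
            bse = np.asarray(res.bse)
        if (not res.converged) or np.any(mu >= 1.0 - 1e-10) or np.any(
                ~np.isfinite(bse)):
            raise RuntimeError("log-binomial fit hit the probability "
                               "boundary or failed to converge")
        with _quiet():
            fit = RateFit(
                beta=pd.Series(res.params, index=X.columns),
                cov_beta=pd.DataFrame(res.cov_params(), index=X.columns,
                                      columns=X.columns),
                model="log-binomial", converged=True,
            )
        label = "risk ratio"
    except Exception as exc:  # boundary failure -> robust Poisson
        fallback_reason = str(exc)
        with _quiet():
            model = sm.GLM(y, X, family=sm.families.Poisson())
            res = model.fit(cov_type="HC1")
        fit = RateFit(
            beta=pd.Series(res.params, index=X.columns),
            cov_beta=pd.DataFrame(res.cov_params(), index=X.columns,
                                  columns=X.columns),
            model="poisson-robust", converged=bool(res.converged),
            fallback_reason=fallback_reason,
        )
        fit.messages.append(
            "log-binomial boundary failure; Poisson model with sandwich "
            "variance used instead")
        label = "risk ratio (robust Poisson)"
    return fit, _effects(fit, tab, totals, ci_level, label)
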