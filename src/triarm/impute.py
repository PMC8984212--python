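"""Multiple imputation by chained equations in wide format, with Rubin
pooling.

The secondary missing-data strategy: each visit's measurement is "just
another variable" in a one-row-per-child wide table, imputed by chained
univariate models — Bayesian linear regression for continuous variables
(normal-inverse-gamma posterior draws) and logistic regression with a
large-sample normal posterior approximation for binary ones — run
separately within each treatment arm. Ferritin is imputed on the natural
log scale. Analyses of the m completed datasets are combined with Rubin's
rules (pooled estimate = mean; total variance = within + (1 + 1/m) x
between) with Barnard-Rubin degrees of freedom.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .dataset import TrialDataset

DEFAULT_M = 5
DEFAULT_ITERATIONS = 10


# ------------------------------------------------------------ descriptives
def missingness_summary(data: TrialDataset, outcomes=("cognitive",
                        "language", "motor", "haemoglobin", "ferritin",
                        "laz", "waz")) -> dict:
    """Missing-data descriptives.

    Returns a dict with ``counts`` (per outcome x visit: n missing, n
    total, percent) and ``baseline_by_missingness`` (baseline child and
    household characteristics summarised separately for children with and
    without an observed cognitive score at each visit).
    """
    tab = data.outcomes
    rows = []
    for outcome in outcomes:
        if outcome not in tab.columns:
            continue
        for visit in (0, 1, 2):
            sub = tab[tab["visit"] == visit]
            n = len(sub)
            n_missing = int(sub[outcome].isna().sum())
            rows.append({
                "outcome": outcome, "visit": visit, "n": n,
                "n_missing": n_missing,
                "pct_missing": 100.0 * n_missing / n if n else np.nan,
            })
    counts = pd.DataFrame(rows)

    base_cols = [c for c in ("maternal_education", "fci_score",
                             "food_insecurity", "wealth_quintile",
                             "age_months") if c in data.children.columns]
    by_missing = []
    for visit in (0, 1, 2):
        sub = tab[tab["visit"] == visit][["child_id", "cognitive"]]
        merged = data.children.merge(sub, on="child_id", how="left")
        merged["missing_cognitive"] = merged["cognitive"].isna()
        summary = merged.groupby("missing_cognitive")[base_cols].agg(
            ["mean", "std"])
        summary["visit"] = visit
        by_missing.append(summary.reset_index())
    return {"counts": counts,
            "baseline_by_missingness": pd.concat(by_missing,
                                                 ignore_index=True)}


def choose_m(missing_percentage: float, default_m: int = DEFAULT_M) -> int:
    """Number of imputations: at least the percentage of missing data.

    m = max(default, ceil(percentage)); e.g. 17.3% missing -> m = 18.
    """
    if not 0.0 <= missing_percentage <= 100.0:
        raise ValueError("missing percentage must lie in [0, 100]")
    return max(default_m, math.ceil(missing_percentage))


# ------------------------------------------------------------------- MICE
@dataclass
class ImputedStack:
    datasets: list                  # m completed wide DataFrames
    m: int
    meta: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.datasets)

    def write(self, directory) -> None:
        """Store the stack as an indexed CSV set plus JSON metadata."""
        import json
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, ds in enumerate(self.datasets, start=1):
            ds.to_csv(directory / f"imputation_{i:03d}.csv", index=False)
        (directory / "imputation_meta.json").write_text(
            json.dumps({"m": self.m, **self.meta}, indent=2))

    @classmethod
    def read(cls, directory) -> "ImputedStack":
        import json
        from pathlib import Path
        directory = Path(directory)
        meta = json.loads(
            (directory / "imputation_meta.json").read_text())
        m = meta.pop("m")
        datasets = [pd.read_csv(directory / f"imputation_{i:03d}.csv")
                    for i in range(1, m + 1)]
        return cls(datasets=datasets, m=m, meta=meta)


def _blr_draw(Xo, yo, Xm, rng):
    """Bayesian linear regression imputation draw (flat prior)."""
    n, q = Xo.shape
    XtX = Xo.T @ Xo
    XtX_inv = np.linalg.pinv(XtX)
    beta_hat = XtX_inv @ (Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    df = max(n - q, 1)
    ssr = float(resid @ resid)
    sigma2 = ssr / rng.chisquare(df) if ssr > 0 else 1e-12
    L = np.linalg.cholesky(XtX_inv * sigma2 + 1e-12 * np.eye(q))
    beta = beta_hat + L @ rng.standard_normal(q)
    return Xm @ beta + np.sqrt(sigma2) * rng.standard_normal(len(Xm))


def _logistic_draw(Xo, yo, Xm, rng):
    """Logistic-regression imputation draw (normal posterior approx)."""
    import statsmodels.api as sm
    if len(np.unique(yo)) < 2:
        # degenerate: all one level among observed -> impute that level
        return np.full(len(Xm), yo[0])
    with np.errstate(all="ignore"):
        res = sm.GLM(yo, Xo, family=sm.families.Binomial()).fit(maxiter=100)
        cov = np.asarray(res.cov_params())
        cov = (cov + cov.T) / 2.0
        try:
            L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))
        except np.linalg.LinAlgError:
            L = np.diag(np.sqrt(np.clip(np.diag(cov), 1e-10, None)))
        beta = np.asarray(res.params) + L @ rng.standard_normal(len(cov))
    p = expit(Xm @ beta)
    return (rng.random(len(Xm)) < p).astype(float)


def mice_jav(wide: pd.DataFrame, m: int, targets, predictors,
             iterations: int = DEFAULT_ITERATIONS, seed: int = 0,
             by: str | None = "arm", binary_targets=(), log_targets=()
             ) -> ImputedStack:
    """Chained-equations multiple imputation on a wide (one row per child)
    table.

    Parameters
    ----------
    targets : incomplete columns to impute, visited in the given
        (chronological) order within every chained iteration.
    predictors : complete covariate columns entering every univariate
        model (non-numeric ones are dummy-coded).
    by : optional grouping column (default "arm"): imputation models are
        fitted separately within each group.
    binary_targets : subset of targets imputed by logistic regression.
    log_targets : subset imputed on the natural-log scale and
        back-transformed (e.g. ferritin).

    Observed cells are identical across the m returned datasets;
    deterministic given ``seed``.
    """
    targets = list(targets)
    for t in targets:
        if t not in wide.columns:
            raise ValueError(f"target column {t!r} absent")
    groups = [None] if by is None else list(pd.unique(wide[by]))
    for g in groups:
        sub = wide if g is None else wide[wide[by] == g]
        for t in targets:
            if sub[t].isna().all():
                raise ValueError(
                    f"column {t!r} is 100% missing within group {g!r}; "
                    f"cannot build an imputation model")

    rng = np.random.default_rng(seed)
    datasets = []
    for _ in range(m):
        completed = wide.copy()
        for g in groups:
            gsel = np.ones(len(wide), bool) if g is None \
                else (wide[by] == g).to_numpy()
            completed.loc[gsel] = _impute_group(
                wide.loc[gsel], targets, predictors, iterations, rng,
                binary_targets, log_targets)
        datasets.append(completed)
    return ImputedStack(datasets=datasets, m=m, meta={
        "seed": int(seed), "iterations": int(iterations),
        "targets": targets, "by": by,
        "binary_targets": list(binary_targets),
        "log_targets": list(log_targets),
    })


def _predictor_matrix(df: pd.DataFrame, cols) -> np.ndarray:
    parts = [np.ones((len(df), 1))]
    for c in cols:
        s = df[c]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.to_numpy(float)[:, None])
        else:
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:
                parts.append((s.astype(str) == lev)
                             .to_numpy(float)[:, None])
    return np.hstack(parts)


def _impute_group(wide, targets, predictors, iterations, rng,
                  binary_targets, log_targets):
    work = wide.copy()
    miss = {t: work[t].isna().to_numpy() for t in targets}
    # transform log-scale targets once
    for t in log_targets:
        with np.errstate(invalid="ignore"):
            work[t] = np.log(pd.to_numeric(work[t]))
    # initial fill: random draws from the observed margin
    for t in targets:
        obs = work.loc[~miss[t], t].to_numpy(float)
        if miss[t].any():
            work.loc[miss[t], t] = rng.choice(obs, size=miss[t].sum())
    if all(not m_.any() for m_ in miss.values()):
        out = work
    else:
        for _ in range(iterations):
            for t in targets:
                if not miss[t].any():
                    continue
                others = [u for u in targets if u != t]
                Xall = np.hstack([
                    _predictor_matrix(work, predictors),
                    work[others].to_numpy(float),
                ]) if others else _predictor_matrix(work, predictors)
                yo = work.loc[~miss[t], t].to_numpy(float)
                Xo, Xm = Xall[~miss[t]], Xall[miss[t]]
                if t in binary_targets:
                    draw = _logistic_draw(Xo, yo, Xm, rng)
                else:
                    draw = _blr_draw(Xo, yo, Xm, rng)
                work.loc[miss[t], t] = draw
        out = work
    for t in log_targets:
        out[t] = np.exp(out[t])
    return out


# ------------------------------------------------------------------ Rubin
@dataclass
class PooledEstimate:
    estimate: float                  # Q-bar
    within_variance: float           # U-bar
    between_variance: float          # B
    total_variance: float            # T = U + (1 + 1/m) B
    df: float
    ci_low: float
    ci_high: float
    ci_level: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


def rubin_pool(estimates, variances, ci_level: float = 0.95,
               df_com: float | None = None) -> PooledEstimate:
    """Pool per-imputation estimates and variances by Rubin's rules.

    T = U-bar + (1 + 1/m) B with B the sample variance of the estimates.
    Degrees of freedom follow the classical large-sample formula, shrunk
    by the Barnard-Rubin correction when the complete-data df ``df_com``
    is supplied; the CI uses the t reference.
    """
    q = np.asarray(estimates, float)
    u = np.asarray(variances, float)
    m = len(q)
    if m < 2 or len(u) != m:
        raise ValueError("need at least two imputations with matching "
                         "variances")
    qbar = float(q.mean())
    ubar = float(u.mean())
    b = float(q.var(ddof=1))
    t = ubar + (1.0 + 1.0 / m) * b
    if b > 0:
        r = (1.0 + 1.0 / m) * b / ubar if ubar > 0 else np.inf
        nu_old = (m - 1) * (1.0 + 1.0 / r) ** 2 if np.isfinite(r) else m - 1
        if df_com is not None:
            lam = (1.0 + 1.0 / m) * b / t
            nu_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
            nu = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
        else:
            nu = nu_old
    else:
        nu = np.inf if df_com is None else float(df_com)
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, nu) if np.isfinite(nu) \
        else stats.norm.ppf(0.5 + ci_level / 2.0)
    half = tcrit * np.sqrt(t)
    return PooledEstimate(
        estimate=qbar, within_variance=ubar, between_variance=b,
        total_variance=float(t), df=float(nu),
        ci_low=float(qbar - half), ci_high=float(qbar + half),
        ci_level=ci_level, m=m)


def to_wide(data: TrialDataset, outcomes) -> pd.DataFrame:
    """One-row-per-child wide table: ``<outcome>_<visit>`` columns plus
    child-level covariates — the layout chained-equations imputation runs
    on."""
    tab = data.outcomes
    pieces = []
    for outcome in outcomes:
        w = tab.pivot(index="child_id", columns="visit", values=outcome)
        w.columns = [f"{outcome}_{v}" for v in w.columns]
        pieces.append(w)
    wide = pd.concat(pieces, axis=1).reset_index()
    return data.children.merge(wide, on="child_id", how="left")
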