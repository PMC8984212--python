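"""Synthetic three-arm trial generator.

Emulates the design of a 1:1:1 randomised supplementation trial in young
children: stratified permuted-block allocation by union and sex,
developmental composites and laboratory outcomes measured at baseline,
month 3 and month 12 with a configurable within-child covariance,
weekly/monthly morbidity reports, daily adherence, and loss to follow-up
under MCAR or MAR. Everything is deterministic given ``SimConfig.seed``.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import (
    ARMS, CONTINUOUS_OUTCOMES, INTERVENTION_DAYS, MORBIDITY_TYPES,
    N_MONTHLY_REPORTS, N_WEEKLY_REPORTS, SEXES, STUDY_DAYS, UNIONS,
    VISIT_DAYS, DropoutSpec, SimConfig,
)
from .dataset import TrialDataset

# weekly reports span the 90-day intervention; the last falls on day 90
WEEKLY_REPORT_DAYS = tuple(7 * w for w in range(1, N_WEEKLY_REPORTS)) + (90,)
MONTHLY_REPORT_DAYS = (120, 150, 180, 210, 240, 270, 300, 330, 365)
assert len(MONTHLY_REPORT_DAYS) == N_MONTHLY_REPORTS


def _permuted_blocks(n: int, block_size: int, rng: np.random.Generator) -> np.ndarray:
    """Arm labels for ``n`` sequential allocations from permuted blocks.

    Each block holds ``block_size/3`` slots per arm in random order; the
    final block is truncated if ``n`` is not a multiple of the block size.
    """
    per_arm = block_size // 3
    n_blocks = -(-n // block_size)
    template = np.repeat(np.arange(3), per_arm)
    out = np.empty(n_blocks * block_size, dtype=int)
    for b in range(n_blocks):
        out[b * block_size:(b + 1) * block_size] = rng.permutation(template)
    return np.asarray(ARMS, dtype=object)[out[:n]]


def generate_randomisation_list(strata, block_size: int, n_per_stratum,
                                seed: int) -> pd.DataFrame:
    """Stratified permuted-block randomisation schedule.

    Parameters
    ----------
    strata : sequence of (union, sex) cells.
    block_size : allocations per block; must be a multiple of 3 so each
        block contains every arm equally often.
    n_per_stratum : mapping cell -> count, or a sequence aligned to strata.
    seed : RNG seed; the schedule is deterministic given the seed.

    Returns
    -------
    DataFrame with columns union, sex, position (1-based within stratum),
    arm.
    """
    if block_size % 3 != 0 or block_size <= 0:
        raise ValueError(
            f"block_size must be a positive multiple of 3 so each permuted "
            f"block balances the three arms; got {block_size}"
        )
    if not isinstance(n_per_stratum, dict):
        n_per_stratum = dict(zip([tuple(s) for s in strata], n_per_stratum))
    rng = np.random.default_rng(seed)
    rows = []
    for stratum in strata:
        union, sex = tuple(stratum)
        n = int(n_per_stratum[(union, sex)])
        if n < 0:
            raise ValueError("per-stratum counts must be non-negative")
        arms = _permuted_blocks(n, block_size, rng)
        rows.append(pd.DataFrame({
            "union": union, "sex": sex,
            "position": np.arange(1, n + 1), "arm": arms,
        }))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["union", "sex", "position", "arm"])


def _draw_children(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = 3 * config.n_per_arm
    cells = list(config.strata_weights)
    weights = np.array([config.strata_weights[c] for c in cells])
    cell_idx = rng.choice(len(cells), size=n, p=weights)
    union = np.array([cells[i][0] for i in cell_idx], dtype=object)
    sex = np.array([cells[i][1] for i in cell_idx], dtype=object)

    # allocate within stratum in recruitment order
    arm = np.empty(n, dtype=object)
    for u in UNIONS:
        for s in SEXES:
            mask = (union == u) & (sex == s)
            arm[mask] = _permuted_blocks(int(mask.sum()), config.block_size, rng)

    children = pd.DataFrame({
        "child_id": [f"C{i:05d}" for i in range(1, n + 1)],
        "arm": arm, "union": union, "sex": sex,
        "age_months": np.round(rng.uniform(8.0, 10.0, n), 1),
        "wealth_quintile": rng.integers(1, 6, n),
        "maternal_education": np.minimum(rng.poisson(5.0, n), 16),
        "food_insecurity": rng.poisson(3.0, n),
        "fci_score": np.round(np.clip(rng.normal(25.0, 5.0, n), 0, 48), 1),
        "rater": rng.integers(1, 5, n).astype(str),
    })

    # registry flags and participation interval
    v = config.violation_rates
    children["consent_withdrawn_all_data"] = rng.random(n) < v.get(
        "consent_withdrawn_all_data", 0.0)
    children["received_any_dose"] = ~(rng.random(n) < v.get("never_dosed", 0.0))
    children["improper_unblinding"] = rng.random(n) < v.get(
        "improper_unblinding", 0.0)
    children["eligibility_violation"] = rng.random(n) < v.get(
        "eligibility_violation", 0.0)

    died = rng.random(n) < config.death_rate
    death_day = np.where(died, rng.integers(1, STUDY_DAYS + 1, n), -1)
    withdraw_day = np.where(
        children["consent_withdrawn_all_data"],
        rng.integers(1, STUDY_DAYS + 1, n), STUDY_DAYS)
    exit_day = np.minimum(np.where(died, death_day, STUDY_DAYS), withdraw_day)
    children["death_day"] = np.where(died, death_day, np.nan)
    children["randomisation_day"] = 0
    children["last_contact_day"] = exit_day
    return children


def _draw_outcomes(config: SimConfig, children: pd.DataFrame,
                   rng: np.random.Generator) -> pd.DataFrame:
    n = len(children)
    arm = children["arm"].to_numpy()
    visit = np.tile([0, 1, 2], n)
    frame = pd.DataFrame({
        "child_id": np.repeat(children["child_id"].to_numpy(), 3),
        "visit": visit,
    })
    # assessment days: nominal visit day plus jitter; a small fraction of
    # follow-up visits land grossly late to exercise the window filter
    jitter_sd = np.array([4.0, 10.0, 14.0])
    days = np.repeat(np.array(VISIT_DAYS, float)[None, :], n, axis=0)
    days += rng.normal(0.0, jitter_sd, size=(n, 3))
    late = rng.random((n, 3)) < 0.01
    late[:, 0] = False
    days += late * rng.uniform(40.0, 120.0, size=(n, 3))
    frame["assessment_day"] = np.clip(np.round(days), 0, None).astype(int).ravel()

    arm_effect = {
        outcome: np.stack([
            np.array([0.0, *config.arm_effect(outcome, a)]) for a in ARMS
        ]) for outcome in CONTINUOUS_OUTCOMES
    }
    arm_index = np.array([ARMS.index(a) for a in arm])

    for outcome in CONTINUOUS_OUTCOMES:
        mean = np.asarray(config.visit_means[outcome], float)[None, :].repeat(n, 0)
        mean = mean + arm_effect[outcome][arm_index]
        L = np.linalg.cholesky(config.within_child_covariance[outcome])
        values = mean + rng.standard_normal((n, 3)) @ L.T
        if outcome in ("ferritin", "crp"):
            values = np.exp(values)
        frame[outcome] = values.ravel()
    return frame


def _draw_morbidity(config: SimConfig, children: pd.DataFrame,
                    rng: np.random.Generator) -> pd.DataFrame:
    report_days = np.array(WEEKLY_REPORT_DAYS + MONTHLY_REPORT_DAYS)
    period = np.array(["intervention"] * N_WEEKLY_REPORTS
                      + ["extended"] * N_MONTHLY_REPORTS, dtype=object)
    n = len(children)
    k = len(report_days)
    frame = pd.DataFrame({
        "child_id": np.repeat(children["child_id"].to_numpy(), k),
        "report_day": np.tile(report_days, n),
        "period": np.tile(period, n),
    })
    # occasions after the child's exit (death/withdrawal) are never observed
    exit_day = np.repeat(children["last_contact_day"].to_numpy(), k)
    observed = frame["report_day"].to_numpy() <= exit_day
    frame["observed"] = observed

    arm = np.repeat(children["arm"].to_numpy(), k)
    for mtype in MORBIDITY_TYPES:
        rate = config.morbidity_rates.get(mtype, 0.0)
        ratios = config.morbidity_rate_ratio.get(mtype, {})
        lam = rate * np.array([ratios.get(a, 1.0) for a in arm])
        if config.morbidity_dispersion:
            size = config.morbidity_dispersion
            counts = rng.negative_binomial(size, size / (size + lam))
        else:
            counts = rng.poisson(lam)
        counts = np.where(observed, counts, 0)
        frame[mtype] = counts
        # clinic visit for this reason, given at least one event
        frame[f"clinic_{mtype}"] = (counts > 0) & (rng.random(n * k) < 0.3)
    frame["hospitalisation"] = observed & (rng.random(n * k) < 0.002)
    frame["sae"] = observed & (rng.random(n * k) < 0.001)
    frame["any_clinic_visit"] = frame[
        [f"clinic_{t}" for t in MORBIDITY_TYPES]].any(axis=1)
    return frame


def _draw_adherence(config: SimConfig, children: pd.DataFrame,
                    rng: np.random.Generator, keep_daily: bool):
    n = len(children)
    a, b = config.adherence_beta
    p = rng.beta(a, b, n)
    has_data = rng.random(n) >= config.prob_no_intake_data
    days_active = np.minimum(
        children["last_contact_day"].to_numpy(), INTERVENTION_DAYS)
    days_active = np.maximum(days_active, 0)

    daily = None
    if keep_daily:
        # full day-by-child indicator matrix, truncated at exit
        day = np.arange(1, INTERVENTION_DAYS + 1)
        took = rng.random((n, INTERVENTION_DAYS)) < p[:, None]
        took &= day[None, :] <= days_active[:, None]
        took &= has_data[:, None]
        intake_days = took.sum(axis=1)
        daily = pd.DataFrame({
            "child_id": np.repeat(children["child_id"].to_numpy(),
                                  INTERVENTION_DAYS),
            "day": np.tile(day, n),
            "took_both": took.ravel(),
        })
    else:
        intake_days = rng.binomial(days_active.astype(int), p)
        intake_days = np.where(has_data, intake_days, 0)
    children = children.copy()
    children["has_intake_data"] = has_data
    children["intake_days"] = intake_days
    return children, daily


def simulate_trial(config: SimConfig) -> TrialDataset:
    """Generate one complete trial (before loss to follow-up).

    Per-arm sizes target ``config.n_per_arm``; within every stratum the
    permuted blocks keep the running arm imbalance at or below two-thirds
    of the block size. Baseline outcome distributions are identical across
    arms by construction; arm effects enter only at visits 1 and 2.
    """
    rng = np.random.default_rng(config.seed)
    children = _draw_children(config, rng)
    outcomes = _draw_outcomes(config, children, rng)
    if config.light:
        morbidity, daily = None, None
        children["has_intake_data"] = True
        children["intake_days"] = 0
    else:
        morbidity = _draw_morbidity(config, children, rng)
        children, daily = _draw_adherence(config, children, rng,
                                          keep_daily=True)
    return TrialDataset(
        children=children, outcomes=outcomes, morbidity=morbidity,
        intake=daily,
        meta={"seed": int(config.seed), "n_per_arm": int(config.n_per_arm),
              "generator": "triarm.synth.simulate_trial"},
    )


def _missingness_probability(data: TrialDataset, dropout: DropoutSpec,
                             baseline: pd.DataFrame) -> np.ndarray:
    """Per-child probability of missing the month-3 visit."""
    n = data.n_children
    if dropout.mechanism == "MCAR":
        return np.full(n, dropout.rate)
    # MAR: logistic in standardised observed baseline quantities, intercept
    # calibrated so the marginal rate matches dropout.rate
    lp = np.zeros(n)
    for name, coef in dropout.mar_predictors.items():
        # "arm:<arm>" is an arm indicator; "arm:<arm>:<var>" interacts it
        # with a standardised baseline quantity — still MAR (all observed)
        if name.startswith("arm:") and name.count(":") == 2:
            _, arm_name, var = name.split(":")
            ind = (data.children["arm"] == arm_name).to_numpy(float)
            if var in data.children.columns:
                v = pd.to_numeric(data.children[var]).to_numpy(float)
            elif var in baseline.columns:
                v = baseline[var].to_numpy(float)
            else:
                raise ValueError(f"MAR predictor {name!r}: {var!r} not found")
            sd = v.std()
            if sd > 0:
                v = (v - v.mean()) / sd
            lp += coef * ind * v
            continue
        if name.startswith("arm:"):
            x = (data.children["arm"] == name.split(":", 1)[1]).to_numpy(float)
        elif name in data.children.columns:
            x = pd.to_numeric(data.children[name]).to_numpy(float)
        elif name in baseline.columns:
            x = baseline[name].to_numpy(float)
        else:
            raise ValueError(
                f"MAR predictor {name!r} not found among child covariates "
                f"or baseline outcomes"
            )
        sd = x.std()
        if sd > 0 and not name.startswith("arm:"):
            x = (x - x.mean()) / sd
        lp += coef * x
    if not 0 < dropout.rate < 1:
        return np.full(n, float(dropout.rate))
    c = brentq(lambda c0: expit(lp + c0).mean() - dropout.rate, -30, 30)
    return expit(lp + c)


def apply_missingness(data: TrialDataset, dropout: DropoutSpec,
                      seed: int) -> TrialDataset:
    """Blank post-baseline outcome visits according to the dropout spec.

    Under MCAR each child independently misses the month-3 assessment with
    probability ``dropout.rate``; under MAR the probability follows a
    logistic model on observed baseline covariates/outcomes (standardised),
    calibrated to the same marginal rate. With ``monotone=True`` a child
    missing month 3 is also missing month 12; otherwise month 12 is an
    independent draw with the same probabilities.
    """
    out = data.copy()
    if dropout.rate == 0:
        return out
    rng = np.random.default_rng(seed)
    wide0 = out.outcomes[out.outcomes["visit"] == 0].set_index("child_id")
    wide0 = wide0.loc[out.children["child_id"]]
    p = _missingness_probability(out, dropout, wide0)
    miss1 = rng.random(len(p)) < p
    if dropout.monotone:
        extra = rng.random(len(p)) < p  # additional month-12-only dropout
        miss2 = miss1 | extra
    else:
        miss2 = rng.random(len(p)) < p
    miss = pd.DataFrame({
        "child_id": out.children["child_id"],
        1: miss1, 2: miss2,
    }).melt(id_vars="child_id", var_name="visit", value_name="_miss")
    tab = out.outcomes.merge(miss, on=["child_id", "visit"], how="left")
    mask = tab["_miss"].eq(True).to_numpy()
    value_cols = [c for c in CONTINUOUS_OUTCOMES if c in out.outcomes.columns]
    out.outcomes.loc[mask, value_cols] = np.nan
    out.meta["dropout"] = {
        "mechanism": dropout.mechanism, "rate": dropout.rate,
        "monotone": dropout.monotone, "seed": int(seed),
    }
    return out
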