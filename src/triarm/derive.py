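"""Derived variables, classifications and analysis populations.

All classification rules are pure and missing-propagating: an absent input
yields an absent output (NaN), never a silent default. Binary indicators
are returned as floats (1.0 / 0.0 / NaN) so they drop cleanly into model
matrices.

Thresholds implemented here:

* anaemia: haemoglobin < 110 g/L (strict);
* iron deficiency: ferritin < 12 µg/L, or ferritin < 30 µg/L when
  C-reactive protein > 5 mg/L (both strict);
* iron-deficiency anaemia: both of the above;
* inflammation: CRP > 5 mg/L;
* stunting / underweight / wasting: the respective z-score < −2;
* complier: overall compliance ≥ 70% (boundary inclusive), with compliance
  assumed 0% when no intake data exist.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import INTERVENTION_DAYS, MORBIDITY_TYPES, STUDY_DAYS, VISIT_DAYS
from .dataset import TrialDataset

HB_ANAEMIA_CUTOFF = 110.0          # g/L
FERRITIN_CUTOFF = 12.0             # µg/L
FERRITIN_CUTOFF_INFLAMED = 30.0    # µg/L when CRP > 5 mg/L
CRP_INFLAMMATION_CUTOFF = 5.0      # mg/L
ZSCORE_CUTOFF = -2.0
COMPLIER_THRESHOLD = 70.0          # percent


def _asarray(x):
    return np.asarray(pd.to_numeric(pd.Series(np.atleast_1d(x)),
                                    errors="coerce"), dtype=float)


def _scalarise(out, like):
    return float(out[0]) if np.isscalar(like) or np.ndim(like) == 0 else out


def classify_anaemia(haemoglobin):
    """Anaemia indicator from haemoglobin in g/L (strict < 110)."""
    hb = _asarray(haemoglobin)
    out = np.where(np.isnan(hb), np.nan, (hb < HB_ANAEMIA_CUTOFF).astype(float))
    return _scalarise(out, haemoglobin)


def classify_inflammation(crp):
    """Inflammation indicator from CRP in mg/L (strict > 5)."""
    c = _asarray(crp)
    out = np.where(np.isnan(c), np.nan,
                   (c > CRP_INFLAMMATION_CUTOFF).astype(float))
    return _scalarise(out, crp)


def classify_iron_deficiency(ferritin, crp):
    """Iron-deficiency indicator from ferritin (µg/L) and CRP (mg/L).

    Deficient when ferritin < 12, or ferritin < 30 with CRP > 5 (the
    inflammation-adjusted cut-off). A missing ferritin is always absent; a
    missing CRP leaves the 12–30 µg/L band indeterminate (absent) but does
    not affect values outside it.
    """
    f, c = _asarray(ferritin), _asarray(crp)
    f, c = np.broadcast_arrays(f, c)
    out = np.full(f.shape, np.nan)
    known_f = ~np.isnan(f)
    out[known_f & (f < FERRITIN_CUTOFF)] = 1.0
    out[known_f & (f >= FERRITIN_CUTOFF_INFLAMED)] = 0.0
    band = known_f & (f >= FERRITIN_CUTOFF) & (f < FERRITIN_CUTOFF_INFLAMED)
    known_c = band & ~np.isnan(c)
    out[known_c] = (c[known_c] > CRP_INFLAMMATION_CUTOFF).astype(float)
    return _scalarise(out, ferritin if np.ndim(ferritin) else crp)


def classify_ida(anaemia, iron_deficient):
    """Iron-deficiency anaemia: logical AND with missing propagation.

    A known False on either side decides the conjunction even when the
    other side is unknown.
    """
    a, d = np.broadcast_arrays(_asarray(anaemia), _asarray(iron_deficient))
    out = np.full(a.shape, np.nan)
    out[(a == 0) | (d == 0)] = 0.0
    out[(a == 1) & (d == 1)] = 1.0
    return _scalarise(out, anaemia if np.ndim(anaemia) else iron_deficient)


# ------------------------------------------------------------------ growth
def synthetic_lms_reference() -> pd.DataFrame:
    """A small synthetic LMS growth-reference table for tests and demos.

    Covers ages 0–730 days in 30-day steps for both sexes and the four
    metrics; smooth, loosely realistic curves. It is *not* an official
    growth standard — real analyses must plug in one via the ``reference``
    argument of :func:`growth_zscore`.
    """
    rows = []
    ages = np.arange(0, 731, 30)
    for sex_i, sex in enumerate(("female", "male")):
        for metric, (m0, m1, s) in {
            "length-for-age": (49.0 + sex_i * 0.8, 38.0, 0.035),
            "weight-for-age": (3.3 + sex_i * 0.15, 9.0, 0.11),
            "weight-for-length": (3.3 + sex_i * 0.15, 9.0, 0.09),
            "head-circumference": (34.0 + sex_i * 0.5, 13.0, 0.03),
        }.items():
            t = ages / 730.0
            M = m0 + m1 * np.sqrt(t)
            L = np.where(metric == "weight-for-age", 0.2, 1.0) * np.ones_like(M)
            rows.append(pd.DataFrame({
                "metric": metric, "sex": sex, "age_days": ages,
                "L": L, "M": M, "S": s,
            }))
    return pd.concat(rows, ignore_index=True)


def growth_zscore(measure, age_days, sex, reference: pd.DataFrame,
                  metric: str):
    """LMS z-score: ((measure/M)**L − 1)/(L·S), or log(measure/M)/S at L=0.

    The (L, M, S) row is taken at the nearest tabulated age at or below the
    child's age within the reference for (metric, sex). Ages or sexes not
    covered raise instead of extrapolating.
    """
    sub = reference[(reference["metric"] == metric)]
    if sub.empty:
        raise ValueError(f"reference has no rows for metric {metric!r}")
    scalar_in = (np.ndim(measure) == 0 and np.ndim(age_days) == 0
                 and np.ndim(sex) == 0)
    measure = np.atleast_1d(np.asarray(measure, float))
    age_days = np.atleast_1d(np.asarray(age_days, float))
    sex_arr = np.atleast_1d(np.asarray(sex, object))
    measure, age_days, sex_arr = np.broadcast_arrays(measure, age_days, sex_arr)
    out = np.full(measure.shape, np.nan)
    for s in np.unique(sex_arr):
        ref = sub[sub["sex"] == s].sort_values("age_days")
        if ref.empty:
            raise ValueError(f"reference has no rows for sex {s!r}")
        ages = ref["age_days"].to_numpy(float)
        sel = sex_arr == s
        a = age_days[sel]
        if np.nanmin(a) < ages[0] or np.nanmax(a) > ages[-1]:
            raise ValueError(
                f"age outside reference range [{ages[0]}, {ages[-1]}] days "
                f"for metric {metric!r}, sex {s!r}; refusing to extrapolate"
            )
        idx = np.searchsorted(ages, a, side="right") - 1
        L = ref["L"].to_numpy(float)[idx]
        M = ref["M"].to_numpy(float)[idx]
        S = ref["S"].to_numpy(float)[idx]
        m = measure[sel]
        if np.any(m[~np.isnan(m)] <= 0):
            raise ValueError("measurements must be positive")
        with np.errstate(invalid="ignore"):
            z = np.where(
                L == 0.0, np.log(m / M) / S,
                ((m / M) ** L - 1.0) / (L * S),
            )
        out[sel] = z
    return float(out[0]) if scalar_in else out


def flag_below(z, cutoff: float = ZSCORE_CUTOFF):
    """Stunting/underweight/wasting style flag: z strictly below cutoff."""
    zz = _asarray(z)
    out = np.where(np.isnan(zz), np.nan, (zz < cutoff).astype(float))
    return _scalarise(out, z)


# ------------------------------------------------------------------ scales
def default_temperament_mapping() -> dict:
    """Synthetic 33-item, 7-scale partition used in tests and demos.

    The real instrument's item-to-scale map is proprietary; this stand-in
    partitions items 1..33 into seven disjoint scales of plausible sizes.
    """
    sizes = [6, 5, 4, 5, 5, 4, 4]
    names = ["positive_emotionality", "negative_emotionality", "fear",
             "social_approach", "orientation", "sleep", "energy_exploration"]
    mapping, item = {}, 1
    for name, k in zip(names, sizes):
        mapping[name] = [f"item{item + j}" for j in range(k)]
        item += k
    return mapping


def score_scales(item_scores: pd.DataFrame, mapping: dict,
                 valid_range=(1, 4)) -> pd.DataFrame:
    """Sum items into summary scales; any missing item blanks its scale.

    ``item_scores`` has one row per record and one column per item;
    ``mapping`` maps scale name -> list of item columns. Items outside
    ``valid_range`` are rejected.
    """
    lo, hi = valid_range
    out = pd.DataFrame(index=item_scores.index)
    for scale, items in mapping.items():
        missing_cols = [i for i in items if i not in item_scores.columns]
        if missing_cols:
            raise ValueError(f"items {missing_cols} absent for scale {scale!r}")
        block = item_scores[items].astype(float)
        observed = block.notna()
        bad = observed & ((block < lo) | (block > hi))
        if bad.to_numpy().any():
            raise ValueError(
                f"item values outside [{lo}, {hi}] in scale {scale!r}")
        sums = block.sum(axis=1)
        sums[~observed.all(axis=1)] = np.nan  # no proration
        out[scale] = sums
    return out


# -------------------------------------------------------------- adherence
def compliance(intake_days, participation_days, has_intake_data=True):
    """Overall compliance percentage and complier flag.

    compliance = 100 · (days both products taken) / (participation days);
    complier means compliance ≥ 70% (inclusive). Children with no intake
    data are assigned 0% and non-complier.
    """
    intake = _asarray(intake_days)
    part = _asarray(participation_days)
    has = np.broadcast_to(np.atleast_1d(has_intake_data), intake.shape)
    intake, part = np.broadcast_arrays(intake, part)
    pct = np.zeros(intake.shape)
    with_data = has & ~np.isnan(intake)
    if np.any(with_data & (part <= 0)):
        raise ValueError("participation_days must be positive when intake "
                         "data exist")
    if np.any(with_data & ((intake < 0) | (intake > part))):
        raise ValueError("intake_days must lie in [0, participation_days]")
    pct[with_data] = 100.0 * intake[with_data] / part[with_data]
    complier = pct >= COMPLIER_THRESHOLD
    if np.isscalar(intake_days) or np.ndim(intake_days) == 0:
        return float(pct[0]), bool(complier[0])
    return pct, complier


@dataclass
class PopulationFlags:
    """Per-child analysis-population membership."""
    table: pd.DataFrame  # child_id, in_itt, in_safety, in_per_protocol,
    #                      complier, overall_compliance

    def series(self, name: str) -> pd.Series:
        return self.table.set_index("child_id")[name]


def assign_populations(data: TrialDataset) -> PopulationFlags:
    """ITT, safety and per-protocol membership plus compliance.

    * ITT: all randomised children except full consent withdrawals;
    * safety: ITT children who received at least one dose (control counts);
    * per-protocol: ITT compliers without protocol violations (eligibility
      violation or improper unblinding).
    Participation duration for compliance is min(last contact, day 90).
    """
    ch = data.children
    participation = np.minimum(
        ch["last_contact_day"].to_numpy(float), INTERVENTION_DAYS)
    participation = np.maximum(participation, 1.0)
    pct, complier = compliance(
        ch["intake_days"].to_numpy(float), participation,
        ch.get("has_intake_data", pd.Series(True, index=ch.index)).to_numpy())
    itt = ~ch["consent_withdrawn_all_data"].to_numpy(bool)
    safety = itt & ch["received_any_dose"].to_numpy(bool)
    violation = (ch["eligibility_violation"].to_numpy(bool)
                 | ch["improper_unblinding"].to_numpy(bool))
    pp = itt & complier & ~violation
    table = pd.DataFrame({
        "child_id": ch["child_id"], "in_itt": itt, "in_safety": safety,
        "in_per_protocol": pp, "complier": complier,
        "overall_compliance": pct,
    })
    return PopulationFlags(table)


# ---------------------------------------------------------------- windows
@dataclass
class VisitWindows:
    """Inclusive (lower, upper) day offsets per visit around nominal days.

    Defaults: baseline day 0 (−14, +14), month 3 = day 90 (±28),
    month 12 = day 365 (±56).
    """
    windows: dict = field(default_factory=lambda: {
        0: (-14, 14), 1: (90 - 28, 90 + 28), 2: (365 - 56, 365 + 56)})

    def __post_init__(self):
        items = sorted(self.windows.items())
        prev_hi = -np.inf
        for visit, (lo, hi) in items:
            if lo > hi:
                raise ValueError(f"window for visit {visit} is empty")
            if lo <= prev_hi:
                raise ValueError("visit windows must be ordered and "
                                 "non-overlapping")
            prev_hi = hi

    def contains(self, visit: int, day) -> np.ndarray:
        lo, hi = self.windows[visit]
        d = np.asarray(day, float)
        return (d >= lo) & (d <= hi)


def window_filter(data: TrialDataset, windows: VisitWindows | None = None):
    """Blank assessments made outside their visit window.

    Returns (filtered dataset, exclusion log). The log lists one record per
    excluded child-visit with the offending assessment day.
    """
    windows = windows or VisitWindows()
    out = data.copy()
    tab = out.outcomes
    ok = np.ones(len(tab), dtype=bool)
    for visit in windows.windows:
        sel = tab["visit"] == visit
        ok[sel.to_numpy()] = windows.contains(
            visit, tab.loc[sel, "assessment_day"])
    value_cols = [c for c in tab.columns
                  if c not in ("child_id", "visit", "assessment_day")]
    excluded = tab.loc[~ok, ["child_id", "visit", "assessment_day"]]
    log = [
        {"child_id": r.child_id, "visit": int(r.visit),
         "assessment_day": int(r.assessment_day), "reason": "outside_window"}
        for r in excluded.itertuples()
    ]
    out.outcomes.loc[~ok, value_cols] = np.nan
    out.meta["window_exclusions"] = len(log)
    return out, log


def write_exclusion_log(log, path):
    with open(path, "w") as fh:
        for rec in log:
            fh.write(json.dumps(rec) + "\n")


# ------------------------------------------------------------ safety aggr
PERIODS = {
    "intervention": (0, INTERVENTION_DAYS),
    "extended": (INTERVENTION_DAYS + 1, STUDY_DAYS),
    "study": (0, STUDY_DAYS),
}


def period_aggregates(data: TrialDataset) -> pd.DataFrame:
    """Per-child, per-period event counts and person-time.

    Periods: intervention days 0–90, extended follow-up days 91–365, study
    days 0–365; counts and person-time are additive over the first two.
    Person-time is the child's observed participation days within the
    period; death or withdrawal truncates it. Also emits per-period
    indicators for death, ≥1 hospitalisation, ≥1 serious adverse event and
    ≥1 clinic visit by reason.
    """
    if data.morbidity is None:
        raise ValueError("dataset has no morbidity reports")
    ch = data.children.set_index("child_id")
    morb = data.morbidity
    death_day = ch["death_day"]
    rep = morb.merge(ch[["death_day"]], left_on="child_id", right_index=True)
    after_death = (rep["observed"]
                   & rep["death_day"].notna()
                   & (rep["report_day"] > rep["death_day"]))
    if after_death.any():
        bad = rep.loc[after_death, "child_id"].iloc[0]
        raise ValueError(
            f"observed morbidity report after death date (child {bad}); "
            f"inconsistent input")

    rows = []
    last = ch["last_contact_day"].to_numpy(float)
    for period, (lo, hi) in PERIODS.items():
        sel = morb[(morb["report_day"] >= lo) & (morb["report_day"] <= hi)
                   & morb["observed"]]
        counts = sel.groupby("child_id")[list(MORBIDITY_TYPES)].sum()
        clinic = sel.groupby("child_id")[
            [f"clinic_{t}" for t in MORBIDITY_TYPES]
            + ["any_clinic_visit", "hospitalisation", "sae"]].any()
        # person-time: observed days inside the half-open interval
        # (start, hi] so intervention + extended partition the study period
        start = 0 if lo == 0 else lo - 1
        ptime = np.clip(np.minimum(last, hi) - start, 0, None)
        agg = pd.DataFrame({
            "child_id": ch.index, "period": period, "person_days": ptime,
            "died": (death_day.notna()
                     & (death_day >= lo) & (death_day <= hi)).to_numpy(),
        })
        agg = agg.merge(counts, on="child_id", how="left")
        agg = agg.merge(clinic, on="child_id", how="left")
        count_cols = list(MORBIDITY_TYPES)
        flag_cols = [f"clinic_{t}" for t in MORBIDITY_TYPES] + [
            "any_clinic_visit", "hospitalisation", "sae"]
        agg[count_cols] = agg[count_cols].fillna(0).astype(int)
        agg[flag_cols] = agg[flag_cols].eq(True)  # absent -> False
        rows.append(agg)
    return pd.concat(rows, ignore_index=True)


# ------------------------------------------------------- derived outcomes
def derive_outcome_table(data: TrialDataset) -> pd.DataFrame:
    """Outcome table augmented with the threshold classifications."""
    tab = data.outcomes.copy()
    tab["anaemia"] = classify_anaemia(tab["haemoglobin"])
    tab["iron_deficient"] = classify_iron_deficiency(tab["ferritin"],
                                                     tab["crp"])
    tab["ida"] = classify_ida(tab["anaemia"], tab["iron_deficient"])
    tab["inflammation"] = classify_inflammation(tab["crp"])
    tab["stunting"] = flag_below(tab["laz"])
    tab["underweight"] = flag_below(tab["waz"])
    tab["wasting"] = flag_below(tab["wlz"])
    tab["log_ferritin"] = np.log(tab["ferritin"])
    return tab
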