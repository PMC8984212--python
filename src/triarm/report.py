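"""CONSORT accounting, output tables and the end-to-end pipeline driver.

Tables mirror the trial's reporting skeletons: baseline characteristics
per arm with no between-group tests; efficacy rows with estimates, CIs at
the assigned level and (for primary / key secondary endpoints only)
unadjusted and adjusted p-values — secondary endpoints carry estimates
and 95% CIs with the p-value cells left empty; morbidity incidence-rate
ratios per infection type and period; and per-period proportions for
death, hospitalisation, serious adverse events and clinic visits.
Every number in a table comes from a serialised model result in the run
manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import derive, impute
from .config import ARMS, MORBIDITY_TYPES, SimConfig
from .dataset import TrialDataset
from .models.cace import estimate_cace
from .models.clda import estimate_effect, fit_clda
from .models.rates import fit_log_binomial, fit_poisson_rate
from .multiplicity import gatekeeper_primary, key_secondary_decisions
from .synth import apply_missingness, simulate_trial

KEY_SECONDARY = (
    ("language", "identity"), ("motor", "identity"),
    ("laz", "identity"), ("waz", "identity"),
    ("haemoglobin", "identity"), ("ferritin", "log"),
)
SECONDARY_CONTINUOUS = (("wlz", "identity"),
                        ("head_circumference", "identity"))
COMPARISONS = (("iron", "placebo"), ("mnp", "placebo"), ("iron", "mnp"))


# ---------------------------------------------------------------- CONSORT
@dataclass
class ConsortCounts:
    randomised: dict                 # arm -> n
    excluded_withdrew_consent: dict  # arm -> n
    never_dosed: dict
    analysed_itt: dict
    analysed_safety: dict
    analysed_per_protocol: dict
    lost_to_followup: dict           # (arm, visit) -> n missing cognitive

    def reconcile(self) -> bool:
        for arm in self.randomised:
            if (self.analysed_itt[arm] + self.excluded_withdrew_consent[arm]
                    != self.randomised[arm]):
                return False
        return True

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["lost_to_followup"] = {
            f"{arm}|visit{v}": n
            for (arm, v), n in self.lost_to_followup.items()}
        return d


def consort(data: TrialDataset, flags: derive.PopulationFlags
            ) -> ConsortCounts:
    """Fully reconciled participant-flow counts.

    randomised = analysed(ITT) + excluded (consent withdrawn for all
    data) in every arm; an unclassifiable child raises.
    """
    ch = data.children.merge(flags.table, on="child_id")
    unclassifiable = ch[~ch["in_itt"] & ~ch["consent_withdrawn_all_data"]]
    if len(unclassifiable):
        raise ValueError(
            f"{len(unclassifiable)} randomised children are neither in the "
            f"ITT population nor excluded with a reason")

    def by_arm(mask):
        return {arm: int((mask & (ch["arm"] == arm)).sum()) for arm in ARMS}

    ltfu = {}
    cog = data.outcomes.pivot(index="child_id", columns="visit",
                              values="cognitive")
    cog = ch[["child_id", "arm", "in_itt"]].merge(
        cog, on="child_id", how="left")
    for arm in ARMS:
        for visit in (1, 2):
            sel = (cog["arm"] == arm) & cog["in_itt"]
            ltfu[(arm, visit)] = int(cog.loc[sel, visit].isna().sum())

    counts = ConsortCounts(
        randomised=by_arm(pd.Series(True, index=ch.index)),
        excluded_withdrew_consent=by_arm(ch["consent_withdrawn_all_data"]),
        never_dosed=by_arm(~ch["received_any_dose"]),
        analysed_itt=by_arm(ch["in_itt"]),
        analysed_safety=by_arm(ch["in_safety"]),
        analysed_per_protocol=by_arm(ch["in_per_protocol"]),
        lost_to_followup=ltfu,
    )
    if not counts.reconcile():
        raise ValueError("CONSORT counts do not reconcile")
    return counts


# ----------------------------------------------------------------- tables
def _mean_sd(x, nd=1):
    x = pd.to_numeric(x, errors="coerce").dropna()
    return f"{x.mean():.{nd}f} ({x.std():.{nd}f})" if len(x) else ""


def _median_iqr(x, nd=1):
    x = pd.to_numeric(x, errors="coerce").dropna()
    if not len(x):
        return ""
    q1, q2, q3 = x.quantile([0.25, 0.5, 0.75])
    return f"{q2:.{nd}f} ({q1:.{nd}f}-{q3:.{nd}f})"


def _n_pct(mask):
    mask = pd.Series(mask).dropna().astype(bool)
    n = len(mask)  # non-missing denominator
    return f"{int(mask.sum())} ({100.0 * mask.mean():.1f})" if n else ""


def table1(data: TrialDataset, flags: derive.PopulationFlags) -> pd.DataFrame:
    """Baseline characteristics per arm; no inferential columns at all."""
    itt = flags.series("in_itt")
    ch = data.children[data.children["child_id"].map(itt).fillna(False)]
    base = data.outcomes[data.outcomes["visit"] == 0].merge(
        ch[["child_id", "arm"]], on="child_id")
    rows = []

    def add(label, fn):
        rows.append({"characteristic": label, **{
            arm: fn(arm) for arm in ARMS}})

    for u in sorted(ch["union"].unique()):
        add(f"Union: {u} - no. (%)",
            lambda a, u=u: _n_pct(ch.loc[ch["arm"] == a, "union"] == u))
    add("Female sex - no. (%)",
        lambda a: _n_pct(ch.loc[ch["arm"] == a, "sex"] == "female"))
    add("Maternal education (years), median (IQR)",
        lambda a: _median_iqr(ch.loc[ch["arm"] == a, "maternal_education"], 0))
    add("Family care indicator score, mean (SD)",
        lambda a: _mean_sd(ch.loc[ch["arm"] == a, "fci_score"]))
    add("Haemoglobin (g/L), mean (SD)",
        lambda a: _mean_sd(base.loc[base["arm"] == a, "haemoglobin"]))
    add("Anaemia - no. (%)",
        lambda a: _n_pct(derive.classify_anaemia(
            base.loc[base["arm"] == a, "haemoglobin"])))
    add("Ferritin (ug/L), median (IQR)",
        lambda a: _median_iqr(base.loc[base["arm"] == a, "ferritin"]))
    add("Cognitive composite, mean (SD)",
        lambda a: _mean_sd(base.loc[base["arm"] == a, "cognitive"]))
    return pd.DataFrame(rows)


def _effect_cell(eff, nd=2):
    if not eff.estimable or np.isnan(eff.estimate):
        return "NE"
    return (f"{eff.estimate:.{nd}f} "
            f"({eff.ci_low:.{nd}f} to {eff.ci_high:.{nd}f})")


def _fmt_p(p):
    return "" if p is None or (isinstance(p, float) and np.isnan(p)) \
        else f"{p:.3f}"


def table2(effect_rows: list) -> pd.DataFrame:
    """Efficacy table from annotated effect rows.

    ``effect_rows`` entries: dict with endpoint, tier ('primary',
    'key_secondary' or 'secondary'), visit, and per-comparison
    EffectEstimate plus optional decisions. Secondary rows never carry
    p-values.
    """
    out = []
    for row in effect_rows:
        rec = {"endpoint": row["endpoint"], "tier": row["tier"],
               "visit": row["visit"]}
        for comp, eff in row["effects"].items():
            rec[f"{comp}: estimate (CI)"] = _effect_cell(eff)
            if row["tier"] == "secondary":
                rec[f"{comp}: p unadj"] = ""
                rec[f"{comp}: p adj"] = ""
            else:
                rec[f"{comp}: p unadj"] = _fmt_p(eff.p_unadjusted)
                rec[f"{comp}: p adj"] = _fmt_p(eff.p_adjusted)
        out.append(rec)
    return pd.DataFrame(out)


def table3(data: TrialDataset, flags: derive.PopulationFlags,
           adjust=("union", "sex")) -> pd.DataFrame:
    """Infectious-morbidity incidence-rate ratios (safety population)."""
    agg = derive.period_aggregates(data)
    safety = flags.series("in_safety")
    agg = agg.merge(data.children[["child_id", "arm", "union", "sex"]],
                    on="child_id")
    agg = agg[agg["child_id"].map(safety).fillna(False)]
    rows = []
    for mtype in MORBIDITY_TYPES[:5]:  # infection types
        for period in ("intervention", "extended", "study"):
            sub = agg[agg["period"] == period]
            rec = {"infection": mtype, "period": period}
            for arm in ARMS:
                rec[arm] = _median_iqr(sub.loc[sub["arm"] == arm, mtype], 0)
            _, effects = fit_poisson_rate(sub, mtype, "person_days",
                                          covariates=adjust)
            for eff in effects:
                comp = "_vs_".join(eff.comparison)
                rec[f"{comp}: IRR (CI)"] = _effect_cell(eff)
                rec[f"{comp}: p"] = _fmt_p(eff.p_unadjusted)
            rows.append(rec)
    return pd.DataFrame(rows)


def table4(data: TrialDataset, flags: derive.PopulationFlags,
           adjust=("union", "sex")) -> pd.DataFrame:
    """Death / SAE / hospitalisation / clinic-visit proportions with
    log-binomial comparisons (safety population)."""
    agg = derive.period_aggregates(data)
    safety = flags.series("in_safety")
    agg = agg.merge(data.children[["child_id", "arm", "union", "sex"]],
                    on="child_id")
    agg = agg[agg["child_id"].map(safety).fillna(False)]
    indicators = [("died", "Children who died"),
                  ("hospitalisation", "Children >=1 hospitalisation"),
                  ("sae", "Children with >=1 SAE"),
                  ("any_clinic_visit", "Children >=1 clinic visit")]
    indicators += [(f"clinic_{t}", f"Clinic visit due to {t}")
                   for t in MORBIDITY_TYPES]
    rows = []
    for col, label in indicators:
        for period in ("intervention", "extended", "study"):
            sub = agg[agg["period"] == period].copy()
            sub[col] = sub[col].astype(float)
            rec = {"outcome": label, "period": period}
            for arm in ARMS:
                rec[arm] = _n_pct(sub.loc[sub["arm"] == arm, col] > 0)
            if sub[col].sum() == 0:
                for comp in COMPARISONS:
                    rec[f"{'_vs_'.join(comp)}: p"] = "NE"
            else:
                _, effects = fit_log_binomial(sub, col, covariates=adjust)
                for eff in effects:
                    comp = "_vs_".join(eff.comparison)
                    rec[f"{comp}: p"] = (_fmt_p(eff.p_unadjusted)
                                         if eff.estimable else "NE")
            rows.append(rec)
    return pd.DataFrame(rows)


# --------------------------------------------------------------- pipeline
def _fit_and_effects(tab, outcome, transform, covariates, ci_levels):
    fit = fit_clda(tab, outcome, transform=transform, covariates=covariates)
    effects = {}
    for visit in (1, 2):
        for comp in COMPARISONS:
            lvl = ci_levels.get(("_vs_".join(comp), visit), 0.95)
            effects[("_vs_".join(comp), visit)] = estimate_effect(
                fit, comp, visit, lvl)
    return fit, effects


def run_pipeline(config: SimConfig, out_dir=None, overall_alpha: float = 0.05,
                 sensitivity=("1a",), per_protocol: bool = True,
                 cace: bool = True, mi: bool = False, safety: bool = True,
                 data: TrialDataset | None = None) -> dict:
    """Execute the full pre-specified analysis on a synthetic (or given)
    trial and return the artefact bundle.

    Stages: simulate -> dropout -> visit windows -> derive -> populations
    -> efficacy models (with the configured sensitivity variants) ->
    multiplicity -> safety models -> tables -> manifest. Writes CSV/JSON
    into ``out_dir`` when given. Deterministic for a fixed config.
    """
    bundle = {}
    if data is None:
        data = simulate_trial(config)
        data = apply_missingness(data, config.dropout, seed=config.seed + 1)
    data, exclusion_log = derive.window_filter(data)
    data.outcomes = derive.derive_outcome_table(data)
    flags = derive.assign_populations(data)
    bundle["consort"] = consort(data, flags)
    itt = flags.series("in_itt")
    tab = data.analysis_table(population=itt)

    # ---- primary outcome and gatekeeping, month 3 and month 12
    primary_fit = fit_clda(tab, "cognitive")
    decisions = {}
    ci_levels = {}
    for visit in (1, 2):
        effs = {comp: estimate_effect(primary_fit, comp, visit, 0.975)
                for comp in COMPARISONS}
        mult = gatekeeper_primary(
            effs[("iron", "placebo")].p_unadjusted,
            effs[("mnp", "placebo")].p_unadjusted,
            effs[("iron", "mnp")].p_unadjusted, overall_alpha)
        decisions[visit] = mult
        for comp in COMPARISONS:
            label = "_vs_".join(comp)
            ci_levels[(label, visit)] = mult[label].ci_level
    bundle["gatekeeping"] = decisions

    # re-estimate primary effects at their assigned CI levels
    effect_rows = []
    primary_effects = {}
    for visit in (1, 2):
        effects = {}
        for comp in COMPARISONS:
            label = "_vs_".join(comp)
            eff = estimate_effect(primary_fit, comp, visit,
                                  ci_levels[(label, visit)])
            d = decisions[visit][label]
            eff.p_adjusted = d.p_adjusted
            if d.assigned_alpha is None:
                eff.p_unadjusted = float("nan")  # suppressed in reporting
            effects[label] = eff
            primary_effects[(label, visit)] = eff
        effect_rows.append({"endpoint": "cognitive", "tier": "primary",
                            "visit": visit, "effects": effects})

    # ---- key secondary family with Hochberg per comparison, per visit
    ks_fits = {}
    for outcome, transform in KEY_SECONDARY:
        ks_fits[outcome] = fit_clda(tab, outcome, transform=transform)
    for visit in (1, 2):
        family_p = {}
        ks_effects = {}
        for comp in COMPARISONS:
            label = "_vs_".join(comp)
            family_p[label] = {}
            for outcome, transform in KEY_SECONDARY:
                eff = estimate_effect(ks_fits[outcome], comp, visit,
                                      ci_levels[(label, visit)])
                family_p[label][outcome] = eff.p_unadjusted
                ks_effects[(outcome, label)] = eff
        ks_dec = key_secondary_decisions(decisions[visit], family_p)
        for outcome, _t in KEY_SECONDARY:
            effects = {}
            for comp in COMPARISONS:
                label = "_vs_".join(comp)
                eff = ks_effects[(outcome, label)]
                d = ks_dec[label][outcome]
                eff.p_adjusted = d.p_adjusted
                if d.assigned_alpha is None:
                    eff.p_unadjusted = float("nan")
                effects[label] = eff
            effect_rows.append({"endpoint": outcome, "tier": "key_secondary",
                                "visit": visit, "effects": effects})

    # ---- secondary continuous endpoints: estimates and 95% CIs only
    for outcome, transform in SECONDARY_CONTINUOUS:
        fit = fit_clda(tab, outcome, transform=transform)
        for visit in (1, 2):
            effects = {"_vs_".join(c): estimate_effect(fit, c, visit, 0.95)
                       for c in COMPARISONS}
            effect_rows.append({"endpoint": outcome, "tier": "secondary",
                                "visit": visit, "effects": effects})
    bundle["effect_rows"] = effect_rows

    # ---- sensitivity analyses
    sens = {}
    if "1a" in sensitivity:
        fit = fit_clda(tab, "cognitive",
                       covariates=("fci_score", "maternal_education"))
        sens["1a"] = {"_vs_".join(c): estimate_effect(fit, c, 1, 0.975)
                      for c in COMPARISONS}
    if "1c" in sensitivity:
        fit = fit_clda(tab, "cognitive", covariates=("rater",))
        sens["1c"] = {"_vs_".join(c): estimate_effect(fit, c, 1, 0.975)
                      for c in COMPARISONS}
    if per_protocol:
        pp = flags.series("in_per_protocol")
        pp_tab = data.analysis_table(population=pp)
        fit = fit_clda(pp_tab, "cognitive")
        sens["per_protocol"] = {
            "_vs_".join(c): estimate_effect(fit, c, 1, 0.975)
            for c in COMPARISONS}
    if cace:
        merged = flags.table.merge(data.children[["child_id", "arm"]],
                                   on="child_id")
        for arm in ("iron", "mnp"):
            sel = merged["arm"] == arm
            itt_eff = primary_effects[(f"{arm}_vs_placebo", 1)]
            sens[f"cace_{arm}"] = estimate_cace(
                itt_eff.estimate, itt_eff.se,
                complier_active=float(merged.loc[sel, "complier"].mean()),
                n_active=int(sel.sum()), comparison=(arm, "placebo"),
                ci_level=itt_eff.ci_level)
    if mi:
        sens["mi"] = _mi_sensitivity(data, itt)
    bundle["sensitivity"] = sens

    # ---- tables
    bundle["table1"] = table1(data, flags)
    bundle["table2"] = table2(effect_rows)
    if safety and data.morbidity is not None:
        bundle["table3"] = table3(data, flags)
        bundle["table4"] = table4(data, flags)

    manifest = {
        "config_hash": hashlib.sha256(
            config.to_json().encode()).hexdigest()[:16],
        "seed": int(config.seed), "overall_alpha": overall_alpha,
        "n_window_exclusions": len(exclusion_log),
        "stages": ["synth", "missingness", "windows", "derive",
                   "populations", "models", "multiplicity", "tables"],
        "models": {
            "primary": primary_fit.to_dict(),
            "key_secondary": {k: f.to_dict() for k, f in ks_fits.items()},
        },
    }
    bundle["manifest"] = manifest

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("table1", "table2", "table3", "table4"):
            if name in bundle:
                bundle[name].to_csv(out_dir / f"{name}.csv", index=False)
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
        (out_dir / "consort.json").write_text(
            json.dumps(bundle["consort"].to_dict(), indent=2))
        (out_dir / "gatekeeping.json").write_text(json.dumps(
            {v: json.loads(d.to_json()) for v, d in decisions.items()},
            indent=2))
        derive.write_exclusion_log(exclusion_log,
                                   out_dir / "exclusions.jsonl")
    return bundle


def _mi_sensitivity(data: TrialDataset, itt: pd.Series,
                    ci_level: float = 0.975) -> dict:
    """Secondary missing-data strategy for the primary outcome."""
    sub = data.copy()
    sub.children = sub.children[
        sub.children["child_id"].map(itt).fillna(False)]
    sub.outcomes = sub.outcomes[
        sub.outcomes["child_id"].isin(sub.children["child_id"])]
    wide = impute.to_wide(sub, ["cognitive"])
    pct = 100.0 * wide["cognitive_1"].isna().mean()
    m = impute.choose_m(pct)
    stack = impute.mice_jav(
        wide, m=m, targets=["cognitive_0", "cognitive_1", "cognitive_2"],
        predictors=["union", "sex", "fci_score", "maternal_education"],
        seed=int(data.meta.get("seed", 0)) + 7)
    out = {}
    for comp in (("iron", "placebo"), ("mnp", "placebo"), ("iron", "mnp")):
        ests, vars_ = [], []
        for completed in stack:
            long = completed.melt(
                id_vars=[c for c in completed.columns
                         if not c.startswith("cognitive_")],
                value_vars=["cognitive_0", "cognitive_1", "cognitive_2"],
                var_name="visit", value_name="cognitive")
            long["visit"] = long["visit"].str.rsplit("_", n=1).str[-1] \
                .astype(int)
            fit = fit_clda(long, "cognitive")
            eff = estimate_effect(fit, comp, 1, ci_level)
            ests.append(eff.estimate)
            vars_.append(eff.se ** 2)
        out["_vs_".join(comp)] = impute.rubin_pool(ests, vars_, ci_level)
    return out
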