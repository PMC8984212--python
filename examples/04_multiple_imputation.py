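"""Sensitivity analysis: chained-equations imputation with Rubin pooling.

Dropout is made missing-at-random with heavier loss among low-baseline
placebo children, which biases a naive complete-case change-score
analysis. Wide-format ("just another variable") imputation by treatment
arm followed by Rubin's rules recovers the truth.
"""

from triarm import DropoutSpec, SimConfig, impute, synth
from triarm.models.clda import estimate_effect, fit_clda

TRUTH = 2.0
config = SimConfig(
    n_per_arm=400, seed=31, light=True,
    effects={"cognitive": {"iron": (TRUTH, TRUTH)}},
    dropout=DropoutSpec(mechanism="MAR", rate=0.30,
                        mar_predictors={"arm:placebo:cognitive": -1.5}))
data = synth.simulate_trial(config)
data = synth.apply_missingness(data, config.dropout, seed=32)

wide = impute.to_wide(data, ["cognitive"])
pct = 100.0 * wide["cognitive_1"].isna().mean()
m = impute.choose_m(pct)
print(f"missing at month 3: {pct:.1f}% -> m = {m} imputations")

stack = impute.mice_jav(
    wide, m=m, targets=["cognitive_0", "cognitive_1", "cognitive_2"],
    predictors=["union", "sex", "fci_score", "maternal_education"],
    seed=33)
ests, vars_ = [], []
for completed in stack:
    long = completed.melt(
        id_vars=[c for c in completed.columns
                 if not c.startswith("cognitive_")],
        value_vars=["cognitive_0", "cognitive_1", "cognitive_2"],
        var_name="visit", value_name="cognitive")
    long["visit"] = long["visit"].str.rsplit("_", n=1).str[-1].astype(int)
    eff = estimate_effect(fit_clda(long, "cognitive"), ("iron", "placebo"), 1)
    ests.append(eff.estimate)
    vars_.append(eff.se ** 2)
pooled = impute.rubin_pool(ests, vars_)

cc = wide.dropna(subset=["cognitive_0", "cognitive_1"])
chg = (cc["cognitive_1"] - cc["cognitive_0"]).groupby(cc["arm"]).mean()
print(f"true effect:            {TRUTH:+.2f}")
print(f"complete-case change:   {chg['iron'] - chg['placebo']:+.2f} (biased)")
print(f"MI-pooled estimate:     {pooled.estimate:+.2f} "
      f"(95% CI {pooled.ci_low:+.2f} to {pooled.ci_high:+.2f}, "
      f"B={pooled.between_variance:.3f})")
# The pooled estimate sits near +2 while the complete-case contrast is
# pulled upward by the selective dropout.
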