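"""Constrained longitudinal model: oracle agreement, invariances,
covariance structures, effects and subgroup machinery."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triarm import SimConfig, synth
from triarm.models.clda import (
    build_sigma, estimate_effect, fit_clda, subgroup_effects,
)


def _ancova_oracle(y0, y1, arm):
    """Closed-form baseline-adjusted ANCOVA via the normal equations."""
    X = np.column_stack([
        np.ones_like(y0), y0,
        (arm == "iron").astype(float), (arm == "mnp").astype(float),
    ])
    beta = np.linalg.solve(X.T @ X, X.T @ y1)
    return {"iron": beta[2], "mnp": beta[3]}


class TestOracles:
    def test_matches_ancova_on_complete_two_visit_data(self,
                                                       two_visit_complete):
        tab, arm, y0, y1 = two_visit_complete
        fit = fit_clda(tab, "y")
        oracle = _ancova_oracle(y0, y1, arm)
        assert abs(fit.beta["iron:visit1"] - oracle["iron"]) < 1e-6
        assert abs(fit.beta["mnp:visit1"] - oracle["mnp"]) < 1e-6

    def test_fixed_diagonal_covariance_decouples_baseline(
            self, three_visit_complete):
        # with zero off-diagonals held fixed and no covariates shared
        # across visits, the baseline carries no information: the month-3
        # effect equals the difference in month-3 means (per-visit least
        # squares oracle)
        tab = three_visit_complete.copy()
        tab["union"] = "Bhulta"
        tab["sex"] = "female"
        diag = np.diag([225.0, 225.0, 225.0])
        fit = fit_clda(tab, "cognitive", fixed_covariance=diag)
        m3 = tab[tab["visit"] == 1]
        means = m3.groupby("arm")["cognitive"].mean()
        assert abs(fit.beta["iron:visit1"]
                   - (means["iron"] - means["placebo"])) < 1e-8
        assert abs(fit.beta["mnp:visit1"]
                   - (means["mnp"] - means["placebo"])) < 1e-8

    def test_agrees_with_mixedlm_under_compound_symmetry(
            self, three_visit_complete):
        # independent implementation: a random-intercept linear mixed
        # model is exactly the compound-symmetry covariance
        import statsmodels.formula.api as smf
        tab = three_visit_complete.copy()
        for t in (1, 2):
            tab[f"v{t}"] = (tab["visit"] == t).astype(float)
            for a in ("iron", "mnp"):
                tab[f"{a}_v{t}"] = ((tab["arm"] == a) & (tab["visit"] == t)
                                    ).astype(float)
        tab["golak"] = (tab["union"] == "Golakandail").astype(float)
        tab["rup"] = (tab["union"] == "Rupganj").astype(float)
        tab["male"] = (tab["sex"] == "male").astype(float)
        md = smf.mixedlm(
            "cognitive ~ v1 + v2 + iron_v1 + iron_v2 + mnp_v1 + mnp_v2 "
            "+ golak + rup + male", tab, groups=tab["child_id"])
        ml = md.fit(reml=False)
        fit = fit_clda(tab, "cognitive", covariance="cs", fallback=False)
        assert abs(fit.beta["iron:visit1"] - ml.params["iron_v1"]) < 1e-4
        assert abs(fit.beta["mnp:visit2"] - ml.params["mnp_v2"]) < 1e-4
        assert abs(fit.loglik - ml.llf) < 1e-3


class TestInvariances:
    def test_translation_changes_only_intercept(self, three_visit_complete):
        tab = three_visit_complete
        fit0 = fit_clda(tab, "cognitive")
        shifted = tab.copy()
        shifted["cognitive"] = shifted["cognitive"] + 50.0
        fit1 = fit_clda(shifted, "cognitive")
        assert abs((fit1.beta["intercept"] - fit0.beta["intercept"]) - 50.0) \
            < 1e-5
        others = [c for c in fit0.beta.index if c != "intercept"]
        assert np.allclose(fit0.beta[others], fit1.beta[others], atol=1e-5)
        assert np.allclose(fit0.sigma, fit1.sigma, atol=1e-4)

    def test_unstructured_loglik_dominates_structured(self):
        cfg = SimConfig(n_per_arm=80, seed=23, light=True)
        data = synth.simulate_trial(cfg)
        data = synth.apply_missingness(data, cfg.dropout, seed=24)
        tab = data.analysis_table()
        un = fit_clda(tab, "cognitive", covariance="unstructured",
                      fallback=False)
        for structure in ("ar1", "toeplitz", "cs"):
            restricted = fit_clda(tab, "cognitive", covariance=structure,
                                  fallback=False)
            assert un.loglik >= restricted.loglik - 1e-6
            assert restricted.structure == structure

    def test_sigma_positive_semidefinite(self, three_visit_complete):
        fit = fit_clda(three_visit_complete, "cognitive")
        assert np.min(np.linalg.eigvalsh(fit.sigma)) > -1e-8

    def test_build_sigma_structures_are_valid(self):
        for structure, k in (("unstructured", 6), ("ar1", 2), ("cs", 2),
                             ("toeplitz", 3)):
            theta = np.linspace(0.1, 0.5, k)
            s = build_sigma(theta, structure)
            assert np.allclose(s, s.T)
            assert np.min(np.linalg.eigvalsh(s)) > 0


class TestEffects:
    def test_effect_is_interaction_contrast(self, three_visit_complete):
        fit = fit_clda(three_visit_complete, "cognitive")
        eff = estimate_effect(fit, ("iron", "placebo"), 1, 0.95)
        assert np.isclose(eff.estimate, fit.beta["iron:visit1"])
        head = estimate_effect(fit, ("iron", "mnp"), 2, 0.95)
        assert np.isclose(head.estimate,
                          fit.beta["iron:visit2"] - fit.beta["mnp:visit2"])

    def test_wider_ci_at_higher_level(self, three_visit_complete):
        fit = fit_clda(three_visit_complete, "cognitive")
        e95 = estimate_effect(fit, ("iron", "placebo"), 1, 0.95)
        e975 = estimate_effect(fit, ("iron", "placebo"), 1, 0.975)
        assert (e975.ci_high - e975.ci_low) > (e95.ci_high - e95.ci_low)

    def test_log_transform_gives_ratio_near_one_under_null(self):
        cfg = SimConfig(n_per_arm=400, seed=31, light=True)
        tab = synth.simulate_trial(cfg).analysis_table()
        fit = fit_clda(tab, "ferritin", transform="log")
        eff = estimate_effect(fit, ("iron", "placebo"), 1, 0.95)
        assert eff.scale == "ratio"
        assert eff.ci_low > 0
        assert 0.8 < eff.estimate < 1.25

    def test_unknown_arm_or_visit_rejected(self, three_visit_complete):
        fit = fit_clda(three_visit_complete, "cognitive")
        with pytest.raises(ValueError):
            estimate_effect(fit, ("iron", "syrup"), 1)
        with pytest.raises(ValueError):
            estimate_effect(fit, ("iron", "placebo"), 0)

    def test_singular_design_names_offender(self, three_visit_complete):
        tab = three_visit_complete.copy()
        tab["dup_sex"] = (tab["sex"] == "male").astype(float)
        with pytest.raises(ValueError, match="dup_sex|sex"):
            fit_clda(tab, "cognitive", covariates=("dup_sex",))


class TestSubgroup:
    def test_sex_subgroup_two_rows_per_comparison_visit(
            self, three_visit_complete):
        fit = fit_clda(three_visit_complete, "cognitive", subgroup="sex")
        rows = subgroup_effects(fit)
        assert len(rows) == 3 * 2 * 2  # comparisons x visits x levels
        assert fit.interaction_test is not None
        assert fit.interaction_test["df"] == 4  # (2-1) arms x visits levels

    def test_identical_subgroup_levels_identical_estimates(self):
        cfg = SimConfig(n_per_arm=60, seed=41, light=True)
        tab = synth.simulate_trial(cfg).analysis_table()
        # duplicate every child under two artificial subgroup labels
        a = tab.copy(); a["grp"] = "g1"
        b = tab.copy(); b["grp"] = "g2"
        b["child_id"] = b["child_id"] + "_dup"
        both = pd.concat([a, b], ignore_index=True)
        fit = fit_clda(both, "cognitive", subgroup="grp")
        rows = subgroup_effects(fit)
        piv = rows.pivot_table(index=["comparison", "visit"],
                               columns="level", values="estimate")
        assert np.allclose(piv["reference"], piv["g2"], atol=1e-5)

    def test_interaction_p_uniform_under_null(self):
        # homogeneous (null) effect: the three-way interaction p-value
        # should be uniform; Kolmogorov-Smirnov sanity check
        pvals = []
        for seed in range(250):
            cfg = SimConfig(n_per_arm=50, seed=1000 + seed, light=True)
            tab = synth.simulate_trial(cfg).analysis_table()
            fit = fit_clda(tab, "cognitive", subgroup="sex")
            pvals.append(fit.interaction_test["p_value"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_fallback_cascade_labels_structure():
    cfg = SimConfig(n_per_arm=40, seed=51, light=True)
    tab = synth.simulate_trial(cfg).analysis_table()
    fit = fit_clda(tab, "cognitive", covariance="ar1", fallback=True)
    assert fit.structure in ("ar1", "toeplitz", "cs", "unstructured")
    assert fit.converged


def test_requires_two_visits():
    cfg = SimConfig(n_per_arm=30, seed=61, light=True)
    tab = synth.simulate_trial(cfg).analysis_table()
    tab.loc[tab["visit"] > 0, "cognitive"] = np.nan
    with pytest.raises(ValueError, match="two or more visits"):
        fit_clda(tab, "cognitive")
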