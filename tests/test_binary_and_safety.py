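"""Binary mixed model, safety rate models and the complier-average
causal effect estimator."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from triarm.models.cace import estimate_cace
from triarm.models.glmm import binary_effects, fit_binary_mixed
from triarm.models.rates import fit_log_binomial, fit_poisson_rate


def _single_visit_binary(n_active, k_active, n_control, k_control):
    rows = []
    for i in range(n_active):
        rows.append((f"a{i:03d}", 1, "iron", float(i < k_active)))
    for i in range(n_control):
        rows.append((f"p{i:03d}", 1, "placebo", float(i < k_control)))
    tab = pd.DataFrame(rows, columns=["child_id", "visit", "arm", "y"])
    tab["union"] = "Bhulta"
    tab["sex"] = "female"
    return tab


class TestBinaryMixed:
    def test_degenerate_model_recovers_crude_prevalence_ratio(self):
        # variance pinned at zero, treatment as the only term: the MLE is
        # the ratio of observed proportions
        tab = _single_visit_binary(200, 40, 200, 20)
        fit = fit_binary_mixed(tab, "y", link="log", var_fixed=0.0,
                               include_baseline=False)
        assert fit.link == "log" and fit.converged
        assert np.isclose(np.exp(fit.beta["iron"]), 2.0, atol=1e-6)

    def test_degenerate_ratio_matches_glm_oracle(self):
        import statsmodels.api as sm
        tab = _single_visit_binary(150, 45, 150, 30)
        fit = fit_binary_mixed(tab, "y", link="logit", var_fixed=0.0,
                               include_baseline=False)
        X = np.column_stack([np.ones(len(tab)),
                             (tab["arm"] == "iron").to_numpy(float)])
        res = sm.GLM(tab["y"].to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        assert np.isclose(fit.beta["iron"], res.params[1], atol=1e-5)

    def test_separation_triggers_logit_fallback_with_label(self):
        tab = _single_visit_binary(60, 60, 60, 10)  # all events in iron arm
        fit = fit_binary_mixed(tab, "y", link="log", var_fixed=0.0,
                               include_baseline=False)
        assert fit.link == "logit"
        assert fit.fallback_reason is not None
        assert fit.ratio_label == "odds ratio"

    def test_random_intercept_fit_on_repeated_outcome(self):
        # two visits per child with a true random intercept; the adaptive
        # quadrature fit should find a clearly positive tau and a negative
        # treatment effect on the log scale
        rng = np.random.default_rng(3)
        n = 300
        arm = np.repeat(["iron", "placebo"], n // 2)
        b = rng.normal(0, 0.8, n)
        rows = []
        for i in range(n):
            for visit in (1, 2):
                eta = -1.2 + b[i] - 0.7 * (arm[i] == "iron")
                rows.append((f"c{i:03d}", visit, arm[i],
                             float(rng.random() < expit(eta))))
        tab = pd.DataFrame(rows, columns=["child_id", "visit", "arm", "y"])
        tab["union"] = "Bhulta"
        tab["sex"] = "female"
        fit = fit_binary_mixed(tab, "y", link="logit",
                               include_baseline=False)
        assert fit.converged
        assert 0.2 < fit.tau < 2.0
        assert fit.beta["iron"] < 0
        effs = binary_effects(fit)
        assert len(effs) == 6
        assert all(e.label == "odds ratio" for e in effs)

    def test_single_level_outcome_rejected(self):
        tab = _single_visit_binary(50, 0, 50, 0)
        with pytest.raises(ValueError, match="single observed level"):
            fit_binary_mixed(tab, "y")


def _per_child_counts():
    rng = np.random.default_rng(7)
    n = 120
    return pd.DataFrame({
        "child_id": [f"c{i:03d}" for i in range(3 * n)],
        "arm": np.repeat(["iron", "mnp", "placebo"], n),
        "union": "Bhulta", "sex": "female",
        "events": np.concatenate([
            rng.poisson(3.0, n), rng.poisson(2.0, n), rng.poisson(2.0, n)]),
        "days": np.full(3 * n, 100.0),
    })


class TestPoissonRate:
    def test_irr_equals_crude_rate_ratio(self):
        tab = _per_child_counts()
        _, effs = fit_poisson_rate(tab, "events", "days")
        totals = tab.groupby("arm")["events"].sum()
        expect = (totals["iron"] / totals["placebo"])
        got = [e for e in effs if e.comparison == ("iron", "placebo")][0]
        assert np.isclose(got.estimate, expect, rtol=1e-8)

    def test_thirty_vs_twenty_events_gives_irr_1p5(self):
        tab = pd.DataFrame({
            "child_id": [f"c{i}" for i in range(200)],
            "arm": np.repeat(["iron", "placebo"], 100),
            "union": "B", "sex": "f",
            "events": np.r_[np.repeat([1, 0], [30, 70]),
                            np.repeat([1, 0], [20, 80])],
            "days": np.full(200, 30.0),  # one child-month each
        })
        _, effs = fit_poisson_rate(tab, "events", "days")
        got = [e for e in effs if e.comparison == ("iron", "placebo")][0]
        assert np.isclose(got.estimate, 1.5, rtol=1e-8)

    def test_doubling_exposure_leaves_irr_unchanged(self):
        tab = _per_child_counts()
        _, effs1 = fit_poisson_rate(tab, "events", "days")
        tab2 = tab.assign(days=tab["days"] * 2)
        _, effs2 = fit_poisson_rate(tab2, "events", "days")
        for a, b in zip(effs1, effs2):
            assert np.isclose(a.estimate, b.estimate, rtol=1e-8)

    def test_zero_events_in_comparison_non_estimable(self):
        tab = _per_child_counts()
        tab.loc[tab["arm"].isin(["iron", "placebo"]), "events"] = 0
        _, effs = fit_poisson_rate(tab, "events", "days")
        ip = [e for e in effs if e.comparison == ("iron", "placebo")][0]
        assert not ip.estimable


class TestLogBinomial:
    def test_saturated_model_recovers_proportion_ratio(self):
        tab = pd.DataFrame({
            "child_id": [f"c{i}" for i in range(300)],
            "arm": np.repeat(["iron", "mnp", "placebo"], 100),
            "union": "B", "sex": "f",
            "y": np.r_[np.repeat([1.0, 0.0], [30, 70]),
                       np.repeat([1.0, 0.0], [10, 90]),
                       np.repeat([1.0, 0.0], [15, 85])],
        })
        fit, effs = fit_log_binomial(tab, "y")
        assert fit.model == "log-binomial"
        got = {e.comparison: e.estimate for e in effs}
        assert np.isclose(got[("iron", "placebo")], 30 / 15, rtol=1e-6)
        assert np.isclose(got[("mnp", "placebo")], 10 / 15, rtol=1e-6)

    def test_agrees_with_likelihood_grid_oracle(self):
        # brute-force grid search over (intercept, treatment, covariate)
        rng = np.random.default_rng(11)
        n = 80
        arm = np.repeat(["iron", "placebo"], n // 2)
        x = rng.integers(0, 2, n).astype(float)
        p = np.exp(-1.6 + 0.5 * (arm == "iron") + 0.3 * x)
        y = (rng.random(n) < p).astype(float)
        tab = pd.DataFrame({"child_id": [f"c{i}" for i in range(n)],
                            "arm": arm, "union": "B", "sex": "f",
                            "y": y, "x": x})
        fit, _ = fit_log_binomial(tab, "y", covariates=("x",))
        b0 = np.linspace(-3.0, -0.5, 51)
        b1 = np.linspace(-1.0, 1.5, 51)
        b2 = np.linspace(-1.0, 1.5, 51)
        B0, B1, B2 = np.meshgrid(b0, b1, b2, indexing="ij")
        eta = (B0[..., None] + B1[..., None] * (arm == "iron")
               + B2[..., None] * x)
        with np.errstate(all="ignore"):
            logp = np.where(y == 1, eta, np.log1p(-np.exp(eta)))
            ll = np.where(np.any(eta >= 0, axis=-1), -np.inf,
                          np.nansum(logp, axis=-1))
        i, j, k = np.unravel_index(np.argmax(ll), ll.shape)
        grid_best = (b0[i], b1[j], b2[k])
        got = (fit.beta["intercept"], fit.beta["iron"], fit.beta["x"])
        for g, o, step in zip(got, grid_best,
                              (b0[1] - b0[0], b1[1] - b1[0], b2[1] - b2[0])):
            assert abs(g - o) <= step

    def test_all_zero_arm_non_estimable_or_fallback(self):
        tab = pd.DataFrame({
            "child_id": [f"c{i}" for i in range(300)],
            "arm": np.repeat(["iron", "mnp", "placebo"], 100),
            "union": "B", "sex": "f",
            "y": np.r_[np.zeros(100),
                       np.repeat([1.0, 0.0], [10, 90]),
                       np.repeat([1.0, 0.0], [15, 85])],
        })
        _, effs = fit_log_binomial(tab, "y")
        ip = [e for e in effs if e.comparison == ("iron", "placebo")][0]
        # a zero-event arm cannot support a finite ratio estimate
        assert (not ip.estimable) or ip.estimate < 0.05


class TestCace:
    def test_iv_ratio_arithmetic(self):
        est = estimate_cace(1.0, 0.2, complier_active=0.8, n_active=500)
        assert np.isclose(est.estimate, 1.25)
        assert not est.weak_instrument

    def test_full_compliance_recovers_itt(self):
        est = estimate_cace(1.7, 0.3, complier_active=1.0, n_active=500)
        assert np.isclose(est.estimate, 1.7)

    def test_null_itt_gives_null_cace(self):
        est = estimate_cace(0.0, 0.2, complier_active=0.8, n_active=500)
        assert est.estimate == 0.0

    def test_weak_instrument_flagged_but_estimated(self):
        est = estimate_cace(1.0, 0.2, complier_active=0.04, n_active=500)
        assert est.weak_instrument
        assert np.isfinite(est.estimate)

    def test_non_positive_complier_difference_rejected(self):
        with pytest.raises(ValueError):
            estimate_cace(1.0, 0.2, complier_active=0.0, n_active=100)
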