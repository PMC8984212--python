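"""Derived-variable rules: threshold classifications, LMS z-scores, scale
scoring, compliance, populations, visit windows, period aggregates."""
import numpy as np
import pandas as pd
import pytest

from triarm import SimConfig, derive, synth
from triarm.derive import (
    PopulationFlags, VisitWindows, assign_populations, classify_anaemia,
    classify_ida, classify_iron_deficiency, compliance,
    default_temperament_mapping, growth_zscore, period_aggregates,
    score_scales, synthetic_lms_reference, window_filter,
)


@pytest.mark.parametrize("hb, expected", [
    (109.0, 1.0),          # just below the cut-off
    (110.0, 0.0),          # boundary: strict inequality
    (109.999, 1.0),
    (130.0, 0.0),
    (np.nan, np.nan),      # missing propagates
])
def test_anaemia_threshold(hb, expected):
    out = classify_anaemia(hb)
    assert np.isnan(out) if np.isnan(expected) else out == expected


@pytest.mark.parametrize("ferritin, crp, expected", [
    (11.9, 1.0, 1.0),      # low ferritin regardless of CRP
    (11.9, np.nan, 1.0),
    (20.0, 6.0, 1.0),      # inflammation-adjusted cut-off
    (20.0, 5.0, 0.0),      # CRP strictly greater than 5
    (35.0, 10.0, 0.0),     # above both cut-offs
    (29.9, 5.01, 1.0),
    (30.0, 10.0, 0.0),     # ferritin boundary strict
    (np.nan, 1.0, np.nan),
    (20.0, np.nan, np.nan),  # indeterminate band with unknown CRP
])
def test_iron_deficiency_rule(ferritin, crp, expected):
    out = classify_iron_deficiency(ferritin, crp)
    assert np.isnan(out) if np.isnan(expected) else out == expected


@pytest.mark.parametrize("a, d, expected", [
    (1.0, 1.0, 1.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0),
    (1.0, np.nan, np.nan), (0.0, np.nan, 0.0),  # known False decides
    (np.nan, np.nan, np.nan),
])
def test_ida_conjunction(a, d, expected):
    out = classify_ida(a, d)
    assert np.isnan(out) if np.isnan(expected) else out == expected


class TestGrowthZscore:
    def test_median_maps_to_zero(self):
        ref = synthetic_lms_reference()
        row = ref[(ref["metric"] == "length-for-age")
                  & (ref["sex"] == "female")].iloc[10]
        z = growth_zscore(row["M"], row["age_days"], "female", ref,
                          "length-for-age")
        assert abs(z) < 1e-12

    def test_unit_power_reduces_to_relative_difference(self):
        ref = pd.DataFrame({"metric": "length-for-age", "sex": "female",
                            "age_days": [0], "L": [1.0], "M": [50.0],
                            "S": [0.04]})
        z = growth_zscore(52.0, 0, "female", ref, "length-for-age")
        assert np.isclose(z, (52.0 - 50.0) / (50.0 * 0.04))

    def test_log_branch_at_l_zero(self):
        ref = pd.DataFrame({"metric": "weight-for-age", "sex": "male",
                            "age_days": [0], "L": [0.0], "M": [10.0],
                            "S": [0.1]})
        z = growth_zscore(11.0, 0, "male", ref, "weight-for-age")
        assert np.isclose(z, np.log(1.1) / 0.1)

    def test_stunting_boundary_strict(self):
        assert derive.flag_below(-2.01) == 1.0
        assert derive.flag_below(-2.00) == 0.0

    def test_out_of_range_age_raises(self):
        ref = synthetic_lms_reference()
        with pytest.raises(ValueError, match="refusing to extrapolate"):
            growth_zscore(60.0, 10_000, "female", ref, "length-for-age")


class TestScaleScoring:
    def test_partition_conserves_total(self):
        mapping = default_temperament_mapping()
        items = sorted({i for its in mapping.values() for i in its})
        assert len(items) == 33
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(1, 5, (20, 33)), columns=items)
        scores = score_scales(df, mapping)
        assert np.allclose(scores.sum(axis=1), df.sum(axis=1))

    def test_minimum_items_give_minimum_sums(self):
        mapping = default_temperament_mapping()
        items = [i for its in mapping.values() for i in its]
        df = pd.DataFrame(1, index=range(3), columns=items)
        scores = score_scales(df, mapping)
        for scale, its in mapping.items():
            assert (scores[scale] == len(its)).all()

    def test_missing_item_blanks_only_its_scale(self):
        mapping = default_temperament_mapping()
        items = [i for its in mapping.values() for i in its]
        df = pd.DataFrame(2.0, index=[0], columns=items)
        first_scale = next(iter(mapping))
        df.loc[0, mapping[first_scale][0]] = np.nan
        scores = score_scales(df, mapping)
        assert np.isnan(scores.loc[0, first_scale])
        assert scores.drop(columns=first_scale).notna().all().all()

    def test_out_of_range_item_rejected(self):
        mapping = {"s": ["i1", "i2"]}
        df = pd.DataFrame({"i1": [5.0], "i2": [2.0]})
        with pytest.raises(ValueError, match="outside"):
            score_scales(df, mapping, valid_range=(1, 4))


class TestCompliance:
    @pytest.mark.parametrize("intake, days, pct, complier", [
        (63, 90, 70.0, True),       # boundary inclusive
        (62, 90, 62 / 90 * 100, False),
        (90, 90, 100.0, True),
        (0, 90, 0.0, False),
    ])
    def test_percentage_and_flag(self, intake, days, pct, complier):
        p, c = compliance(intake, days)
        assert np.isclose(p, pct) and c == complier

    def test_no_intake_data_means_zero(self):
        p, c = compliance(np.nan, 90, has_intake_data=False)
        assert p == 0.0 and not c

    def test_invalid_participation_rejected(self):
        with pytest.raises(ValueError):
            compliance(10, 0)
        with pytest.raises(ValueError):
            compliance(100, 90)


class TestPopulations:
    def test_membership_rules(self, trial):
        flags = assign_populations(trial)
        merged = trial.children.merge(flags.table, on="child_id")
        # never-dosed children stay in ITT but leave safety
        nd = merged[~merged["received_any_dose"]
                    & ~merged["consent_withdrawn_all_data"]]
        if len(nd):
            assert nd["in_itt"].all() and not nd["in_safety"].any()
        # full consent withdrawal excludes from every population
        cw = merged[merged["consent_withdrawn_all_data"]]
        if len(cw):
            assert not cw[["in_itt", "in_safety", "in_per_protocol"]] \
                .any().any()
        # nesting
        assert (merged["in_per_protocol"] <= merged["in_itt"]).all()
        assert (merged["in_safety"] <= merged["in_itt"]).all()
        assert merged["overall_compliance"].between(0, 100).all()

    def test_clean_complier_in_all_populations(self, trial):
        flags = assign_populations(trial)
        merged = trial.children.merge(flags.table, on="child_id")
        clean = merged[merged["complier"] & merged["received_any_dose"]
                       & ~merged["consent_withdrawn_all_data"]
                       & ~merged["eligibility_violation"]
                       & ~merged["improper_unblinding"]]
        assert len(clean) > 0
        assert clean[["in_itt", "in_safety", "in_per_protocol"]].all().all()


class TestWindows:
    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            VisitWindows({0: (10, 5)})
        with pytest.raises(ValueError):
            VisitWindows({0: (-14, 100), 1: (62, 118)})

    def test_nominal_days_untouched_late_excluded(self, trial):
        filtered, log = window_filter(trial)
        tab = trial.outcomes
        late = tab[(tab["visit"] == 1) & (tab["assessment_day"] > 118)]
        assert len(log) >= len(late)
        fil = filtered.outcomes
        assert fil.loc[late.index, "cognitive"].isna().all()
        on_time = tab[(tab["visit"] == 1)
                      & tab["assessment_day"].between(62, 118)]
        pd.testing.assert_series_equal(
            fil.loc[on_time.index, "cognitive"],
            tab.loc[on_time.index, "cognitive"])

    def test_month3_day200_excluded(self, trial):
        rec = trial.copy()
        idx = rec.outcomes[(rec.outcomes["visit"] == 1)].index[0]
        rec.outcomes.loc[idx, "assessment_day"] = 200
        filtered, log = window_filter(rec)
        assert np.isnan(filtered.outcomes.loc[idx, "cognitive"])
        assert any(e["assessment_day"] == 200 for e in log)

    def test_widening_windows_monotone(self, trial):
        narrow, _ = window_filter(trial, VisitWindows(
            {0: (-5, 5), 1: (80, 100), 2: (350, 380)}))
        wide, _ = window_filter(trial, VisitWindows(
            {0: (-20, 20), 1: (50, 130), 2: (300, 430)}))
        assert (wide.outcomes["cognitive"].notna().sum()
                >= narrow.outcomes["cognitive"].notna().sum())


class TestPeriodAggregates:
    def test_partition_conservation(self, trial):
        agg = period_aggregates(trial)
        piv = agg.pivot(index="child_id", columns="period")
        for t in ("fever", "diarrhoea", "cough"):
            total = piv[(t, "intervention")] + piv[(t, "extended")]
            assert (total == piv[(t, "study")]).all()
        pt = (piv[("person_days", "intervention")]
              + piv[("person_days", "extended")])
        assert np.allclose(pt, piv[("person_days", "study")])

    def test_early_exit_truncates_person_time(self, trial):
        rec = trial.copy()
        cid = rec.children["child_id"].iloc[0]
        rec.children.loc[rec.children["child_id"] == cid,
                         "last_contact_day"] = 45
        rec.morbidity.loc[(rec.morbidity["child_id"] == cid)
                          & (rec.morbidity["report_day"] > 45),
                          "observed"] = False
        agg = period_aggregates(rec)
        mine = agg[agg["child_id"] == cid].set_index("period")
        assert mine.loc["intervention", "person_days"] == 45
        assert mine.loc["extended", "person_days"] == 0

    def test_report_after_death_rejected(self, trial):
        rec = trial.copy()
        cid = rec.children["child_id"].iloc[0]
        rec.children.loc[rec.children["child_id"] == cid, "death_day"] = 10.0
        # keep a later report marked observed -> inconsistent
        assert (rec.morbidity["child_id"] == cid).any()
        with pytest.raises(ValueError, match="death"):
            period_aggregates(rec)

    def test_intervention_fever_count_matches_weekly_reports(self, trial):
        agg = period_aggregates(trial)
        morb = trial.morbidity
        manual = morb[(morb["period"] == "intervention") & morb["observed"]] \
            .groupby("child_id")["fever"].sum()
        got = agg[agg["period"] == "intervention"] \
            .set_index("child_id")["fever"]
        assert (got.reindex(manual.index) == manual).all()
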