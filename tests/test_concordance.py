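"""Concordance groups, proportion formulas, and aggregation."""

import numpy as np
import pandas as pd
import pytest

import bpscreen as b
from bpscreen.concordance import GROUPS
from helpers import bp_records


class TestClassification:
    def test_two_by_two_mapping(self):
        # rows engineered so the 'second' rule hits all four cells:
        #   (standard, simplified) -> group
        df = bp_records([
            (150, 150, 150, 95, 95, 95),   # (+,+) consistent_htn
            (150, 120, 170, 95, 70, 110),  # (+,-) missed (std mean 145/90)
            (120, 150, 110, 70, 95, 65),   # (-,+) over_diagnosed
            (120, 120, 120, 70, 70, 70),   # (-,-) consistent_non_htn
        ])
        out = b.classify(df, ["second"])
        assert list(out["group"]) == ["consistent_htn", "missed",
                                      "over_diagnosed", "consistent_non_htn"]

    def test_missed_implies_standard_positive(self, eligible_cohort):
        cls = b.classify(eligible_cohort)
        assert cls.loc[cls["group"] == "missed", "standard_htn"].all()
        assert not cls.loc[cls["group"] == "over_diagnosed", "standard_htn"].any()

    def test_partition_sums_to_sample_size(self, eligible_cohort):
        cls = b.classify(eligible_cohort)
        per_approach = cls.groupby("approach_id").size()
        assert (per_approach == len(eligible_cohort)).all()

    def test_standard_cannot_be_compared_to_itself(self, eligible_cohort):
        with pytest.raises(b.ConfigError):
            b.classify(eligible_cohort, ["standard"])


class TestProportions:
    @pytest.mark.parametrize("n_missed,n_cons,expected", [
        (5, 95, 5.0), (0, 50, 0.0), (7, 43, 14.0),
    ])
    def test_missed_proportion_formula(self, n_missed, n_cons, expected):
        assert b.missed_proportion(n_missed, n_cons) == pytest.approx(expected)

    @pytest.mark.parametrize("n_over,n_cons,expected", [
        (3, 97, 3.0), (0, 50, 0.0), (11, 89, 11.0),
    ])
    def test_over_proportion_formula(self, n_over, n_cons, expected):
        assert b.over_proportion(n_over, n_cons) == pytest.approx(expected)

    def test_zero_denominator_is_missing_not_zero(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(b.missed_proportion(0, 0))
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(b.over_proportion(0, 0))

    def test_conservation_standard_positive_count(self, eligible_cohort):
        # missed + consistent_htn partitions the standard-positive set
        n_std_pos = int(b.diagnose(eligible_cohort, "standard").hypertensive.sum())
        counts = b.concordance_counts(b.classify(eligible_cohort))
        per_approach = counts.groupby("approach_id")[
            ["n_missed", "n_consistent_htn"]].sum().sum(axis=1)
        assert (per_approach == n_std_pos).all()


def country_row(country, p_missed, region="R1", approach="second"):
    return dict(approach_id=approach, region=region, country=country,
                n_missed=1, n_over=1, n_consistent_htn=9, n_consistent_non_htn=89,
                p_missed=p_missed, p_over=10.0)


class TestAggregation:
    def test_mean_median_min_max(self):
        tbl = pd.DataFrame([country_row(f"C{i}", p) for i, p in enumerate([4, 6, 8])])
        out = b.aggregate(tbl, "global").iloc[0]
        assert out["missed_mean"] == 6 and out["missed_median"] == 6
        assert out["missed_min"] == 4 and out["missed_max"] == 8

    def test_skewed_proportions_mean_differs_from_median(self):
        tbl = pd.DataFrame([country_row(f"C{i}", p) for i, p in enumerate([1, 1, 13])])
        out = b.aggregate(tbl, "global").iloc[0]
        assert out["missed_mean"] == pytest.approx(5.0)
        assert out["missed_median"] == pytest.approx(1.0)

    def test_single_country_sd_is_missing(self):
        out = b.aggregate(pd.DataFrame([country_row("C1", 7.0)]), "global").iloc[0]
        assert out["missed_mean"] == out["missed_median"] == out["missed_min"] == 7.0
        assert np.isnan(out["missed_sd"])

    def test_sd_uses_n_minus_one(self):
        tbl = pd.DataFrame([country_row(f"C{i}", p) for i, p in enumerate([4.0, 8.0])])
        out = b.aggregate(tbl, "global").iloc[0]
        assert out["missed_sd"] == pytest.approx(np.std([4, 8], ddof=1))

    def test_region_level_grouping(self, eligible_cohort):
        tbl = b.country_proportions(b.concordance_counts(b.classify(eligible_cohort)))
        reg = b.aggregate(tbl, "region")
        assert set(reg["region"]) == set(eligible_cohort["region"])
        # pooled counts reconcile with the global aggregation
        glob = b.aggregate(tbl, "global")
        for a in glob["approach_id"]:
            assert (reg.loc[reg.approach_id == a, "n_missed"].sum()
                    == glob.loc[glob.approach_id == a, "n_missed"].iloc[0])

    def test_across_country_mean_is_unweighted(self):
        # one tiny and one huge country: across-country mean ignores size
        tbl = pd.DataFrame([
            dict(approach_id="second", region="R1", country="C1",
                 n_missed=1, n_over=0, n_consistent_htn=9, n_consistent_non_htn=90,
                 p_missed=10.0, p_over=0.0),
            dict(approach_id="second", region="R1", country="C2",
                 n_missed=0, n_over=0, n_consistent_htn=10_000, n_consistent_non_htn=90_000,
                 p_missed=0.0, p_over=0.0),
        ])
        out = b.aggregate(tbl, "global").iloc[0]
        assert out["missed_mean"] == pytest.approx(5.0)
        assert out["pooled_p_missed"] == pytest.approx(100 * 1 / 10_010)

    def test_empty_table_errors(self):
        with pytest.raises(b.ConfigError):
            b.aggregate(pd.DataFrame(), "global")
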