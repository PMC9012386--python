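"""Screening-rule engine: worked examples, boundaries, and the oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import bpscreen as b
from helpers import bp_records, brute_force_diagnoses, reading_grid


class TestEffectiveBP:
    def test_standard_is_unrounded_mean_of_last_two(self):
        df = bp_records([(150, 144, 138, 95, 91, 87)])
        d = b.diagnose(df, "standard")
        assert d.effective_sbp.iloc[0] == pytest.approx(141.0)
        assert d.effective_dbp.iloc[0] == pytest.approx(89.0)
        assert d.readings_used.iloc[0] == 2

    def test_window_not_entered_falls_back_to_first_reading(self):
        # first reading 128/78 sits below the 130-145/80-95 window
        df = bp_records([(128, 150, 150, 78, 95, 95)])
        d = b.diagnose(df, "second_if_130_145_80_95")
        assert d.effective_sbp.iloc[0] == 128
        assert d.effective_dbp.iloc[0] == 78
        assert not d.hypertensive.iloc[0]
        assert d.readings_used.iloc[0] == 1

    def test_window_entered_by_sbp_alone_uses_second_reading(self):
        # SBP 132 inside 130-145 even though DBP 78 < 80 (OR-combined)
        df = bp_records([(132, 150, 120, 78, 95, 70)])
        d = b.diagnose(df, "second_if_130_145_80_95")
        assert d.effective_sbp.iloc[0] == 150
        assert d.effective_dbp.iloc[0] == 95
        assert d.hypertensive.iloc[0]
        assert d.readings_used.iloc[0] == 2

    @pytest.mark.parametrize("approach,expected_used", [
        ("first", 1), ("second", 1), ("avg_first_two", 2), ("standard", 2),
    ])
    def test_readings_used_for_fixed_rules(self, approach, expected_used):
        df = bp_records([(120, 120, 120, 80, 80, 80)])
        assert b.diagnose(df, approach).readings_used.iloc[0] == expected_used

    def test_missing_reading_raises_never_imputes(self):
        df = bp_records([(150, 144, 138, 95, 91, 87)])
        df.loc[0, "sbp3"] = np.nan
        with pytest.raises(b.IncompleteRecordError):
            b.diagnose(df, "standard")

    def test_unknown_approach_id_is_a_config_error(self):
        with pytest.raises(b.ConfigError, match="unknown approach"):
            b.get_approach("third_reading_only")


class TestDiagnosisThresholds:
    def test_cutoffs_are_inclusive(self):
        assert b.is_hypertensive(140.0, 85.0)
        assert b.is_hypertensive(120.0, 90.0)
        assert not b.is_hypertensive(139.9, 89.9)

    def test_threshold_rule_can_miss_a_sustained_elevation(self):
        # first reading below 140/90 -> the >=140/90 trigger never fires and
        # reading 1 decides, even though readings 2-3 are clearly elevated
        df = bp_records([(138, 160, 160, 88, 100, 100)])
        assert not b.diagnose(df, "second_if_ge_140_90").hypertensive.iloc[0]
        assert b.diagnose(df, "standard").hypertensive.iloc[0]

    def test_effective_bp_not_rounded_before_comparison(self):
        # mean of 139 and 140 is 139.5: below 140, must stay non-hypertensive
        df = bp_records([(120, 139, 140, 70, 70, 70)])
        assert not b.diagnose(df, "standard").hypertensive.iloc[0]


class TestOracleEquivalence:
    def test_engine_matches_brute_force_on_boundary_grid(self):
        """Spot-check grid (step 3) against the independent scalar oracle;
        the exhaustive step-1 sweep runs in the acceptance suite."""
        rows = [
            (s1, s2, s3, d1, d2, d3)
            for s1 in range(118, 163, 3)
            for d1 in range(72, 109, 3)
            for (s2, d2) in [(139, 89), (140, 90)]
            for (s3, d3) in [(125, 75), (152, 96)]
        ]
        df = bp_records(rows)
        engine = b.diagnose_all(df)
        for i, row in enumerate(rows):
            expected = brute_force_diagnoses(*row)
            for rule, val in expected.items():
                assert engine[rule].iloc[i] == val, (row, rule)

    @given(
        sbp=st.floats(min_value=80, max_value=220),
        dbp=st.floats(min_value=50, max_value=130),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_identical_readings_make_all_rules_agree(self, sbp, dbp):
        df = bp_records([(sbp, sbp, sbp, dbp, dbp, dbp)])
        flags = b.diagnose_all(df).iloc[0]
        assert flags.nunique() == 1


class TestSetNesting:
    def test_missed_and_over_sets_nest_on_a_cohort(self, eligible_cohort):
        cls = b.classify(eligible_cohort)
        missed = {
            a: set(g.loc[g["group"] == "missed", "person_id"])
            for a, g in cls.groupby("approach_id")
        }
        over = {
            a: set(g.loc[g["group"] == "over_diagnosed", "person_id"])
            for a, g in cls.groupby("approach_id")
        }
        thr = ["second", "second_if_ge_130_80", "second_if_ge_135_85", "second_if_ge_140_90"]
        for lo, hi in zip(thr, thr[1:]):
            assert missed[lo] <= missed[hi]
            assert over[hi] <= over[lo]
        win = ["second_if_130_145_80_95", "second_if_130_150_80_100",
               "second_if_130_155_80_105"]
        for lo, hi in zip(win, win[1:]):
            assert missed[lo] <= missed[hi]


def test_custom_window_approach_definable():
    spec = b.ApproachSpec("custom", "window 120-150/75-95", "window",
                          sbp_low=120, sbp_high=150, dbp_low=75, dbp_high=95)
    df = bp_records([(125, 160, 120, 70, 95, 70)])
    assert b.diagnose(df, spec).hypertensive.iloc[0]
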