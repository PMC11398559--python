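"""Scoring of daily CFS values, trajectory assembly and DLT tallies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pshtraj.scoring import (
    DEFAULT_RUBRICS,
    DLT_INDICATOR_NAMES,
    CategoryRubric,
    DailyCFS,
    DLTRecord,
    InsufficientDataError,
    SymptomDayFlags,
    build_trajectory,
    daily_cfs,
    dlt_tally,
    score_symptom_category,
    score_vital_category,
    window_vitals,
)

ADM = pd.Timestamp("2020-03-01 08:00:00")


def _samples(rows):
    return pd.DataFrame(rows, columns=["patient_id", "timestamp", "parameter", "value"])


class TestWindowVitals:
    def test_half_open_24h_windows_take_daily_maximum(self):
        samples = _samples(
            [
                ("a", ADM + pd.Timedelta(hours=2), "HR", 110.0),
                ("a", ADM + pd.Timedelta(hours=20), "HR", 132.0),
                ("a", ADM + pd.Timedelta(hours=30), "HR", 95.0),
            ]
        )
        out = window_vitals(samples, {"a": ADM})
        assert out["a"][0]["HR"] == 132.0
        assert out["a"][1]["HR"] == 95.0

    def test_sample_exactly_at_day_boundary_enters_next_day(self):
        samples = _samples([("a", ADM + pd.Timedelta(hours=24), "HR", 90.0)])
        out = window_vitals(samples, {"a": ADM})
        assert out["a"] == {1: {"HR": 90.0}}

    def test_empty_input_gives_empty_map(self):
        assert window_vitals(_samples([]), {"a": ADM}) == {}

    def test_absent_parameter_is_absent_not_zero(self):
        samples = _samples([("a", ADM, "HR", 80.0)])
        out = window_vitals(samples, {"a": ADM})
        assert "SBP" not in out["a"][0]

    def test_pre_admission_samples_dropped_with_warning(self, caplog):
        samples = _samples(
            [
                ("a", ADM - pd.Timedelta(hours=1), "HR", 100.0),
                ("a", ADM + pd.Timedelta(hours=1), "HR", 80.0),
            ]
        )
        with caplog.at_level("WARNING", logger="pshtraj.scoring"):
            out = window_vitals(samples, {"a": ADM})
        assert out["a"][0]["HR"] == 80.0
        assert "before admission" in caplog.text

    def test_samples_beyond_n_days_ignored(self):
        samples = _samples(
            [
                ("a", ADM + pd.Timedelta(days=13, hours=1), "HR", 99.0),
                ("a", ADM + pd.Timedelta(days=14, hours=1), "HR", 150.0),
            ]
        )
        out = window_vitals(samples, {"a": ADM}, n_days=14)
        assert out["a"] == {13: {"HR": 99.0}}

    def test_unparseable_timestamp_is_a_hard_error_naming_the_record(self):
        samples = _samples([("a", "not-a-time", "HR", 80.0)])
        with pytest.raises(ValueError, match="not-a-time"):
            window_vitals(samples, {"a": ADM})

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = [
            ("a", ADM + pd.Timedelta(hours=float(h)), p, float(v))
            for h, p, v in zip(
                rng.uniform(0, 72, 40),
                rng.choice(["HR", "SBP", "RR", "TEMP"], 40),
                rng.uniform(40, 180, 40),
            )
        ]
        base = window_vitals(_samples(rows), {"a": ADM})
        shuffled = _samples(rows).sample(frac=1, random_state=1)
        assert window_vitals(shuffled, {"a": ADM}) == base

    def test_fourteen_synthetic_days_give_indices_0_to_13(self, small_cohort):
        pid = small_cohort.vitals["patient_id"].iloc[0]
        vit = small_cohort.vitals[small_cohort.vitals["patient_id"] == pid]
        adm = {pid: vit["timestamp"].min()}
        out = window_vitals(vit, adm, n_days=14)
        assert sorted(out[pid]) == list(range(14))


class TestCategoryScoring:
    @pytest.mark.parametrize(
        "value,expected",
        [(99.9, 0), (100.0, 1), (119.9, 1), (120.0, 2), (125.0, 2), (140.0, 3), (200.0, 3)],
    )
    def test_hr_bands_left_closed(self, value, expected):
        assert score_vital_category(value, DEFAULT_RUBRICS["HR"]) == expected

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError):
            score_vital_category(0.0, DEFAULT_RUBRICS["HR"])

    def test_invalid_rubric_rejected(self):
        with pytest.raises(ValueError):
            CategoryRubric("HR", (120.0, 100.0, 140.0))

    @settings(deadline=None, max_examples=200)
    @given(
        cuts=st.lists(
            st.floats(1, 500, allow_nan=False), min_size=3, max_size=3, unique=True
        ),
        values=st.lists(st.floats(0.1, 600, allow_nan=False), min_size=2, max_size=2),
    )
    def test_monotone_in_value_for_any_rubric(self, cuts, values):
        rubric = CategoryRubric("HR", tuple(sorted(cuts)))
        lo, hi = sorted(values)
        assert score_vital_category(lo, rubric) <= score_vital_category(hi, rubric)

    def test_symptom_rule(self):
        assert score_symptom_category(True) == 2
        assert score_symptom_category(False) == 0


class TestDailyCFS:
    def test_all_top_bands_and_both_mentions_total_16(self, rubrics):
        maxima = {"HR": 150.0, "SBP": 190.0, "RR": 35.0, "TEMP": 39.5}
        flags = SymptomDayFlags("a", 3, True, True)
        rec = daily_cfs(maxima, flags, rubrics)
        assert rec.total == 16 and not rec.missing_categories

    def test_no_data_no_mentions_total_0_with_4_missing(self, rubrics):
        rec = daily_cfs({}, SymptomDayFlags("a", 0), rubrics)
        assert rec.total == 0
        assert rec.missing_categories == frozenset({"HR", "SBP", "RR", "TEMP"})

    def test_hr_band2_others_band0_sweating_total_4(self, rubrics):
        maxima = {"HR": 125.0, "SBP": 120.0, "RR": 14.0, "TEMP": 36.5}
        rec = daily_cfs(maxima, SymptomDayFlags("a", 1, sweating_mentioned=True), rubrics)
        assert rec.total == 4
        assert rec.sub_scores == {
            "HR": 2, "SBP": 0, "RR": 0, "TEMP": 0, "SWEATING": 2, "POSTURING": 0,
        }

    def test_total_equals_sum_and_bounds_on_fuzzed_inputs(self, rubrics):
        rng = np.random.default_rng(5)
        for _ in range(200):
            maxima = {
                cat: float(v)
                for cat, v in zip(
                    ("HR", "SBP", "RR", "TEMP"),
                    rng.uniform([40, 80, 6, 35], [220, 260, 60, 43]),
                )
                if rng.random() > 0.2
            }
            flags = SymptomDayFlags("a", 0, bool(rng.random() < 0.5), bool(rng.random() < 0.5))
            rec = daily_cfs(maxima, flags, rubrics)
            assert rec.total == sum(rec.sub_scores.values())
            assert 0 <= rec.total <= 18
            assert all(s in (0, 1, 2, 3) for s in rec.sub_scores.values())
            assert rec.sub_scores["SWEATING"] in (0, 2)

    def test_inconsistent_total_rejected_by_type(self):
        with pytest.raises(ValueError):
            DailyCFS("a", 0, dict.fromkeys(
                ("HR", "SBP", "RR", "TEMP", "SWEATING", "POSTURING"), 1), 99, frozenset())


def _day(pid, d, total):
    sub = dict.fromkeys(("HR", "SBP", "RR", "TEMP", "SWEATING", "POSTURING"), 0)
    # put the total into vitals 3 points at a time (totals <= 12 in these tests)
    rest = total
    for cat in ("HR", "SBP", "RR", "TEMP"):
        sub[cat] = min(rest, 3)
        rest -= sub[cat]
    return DailyCFS(pid, d, sub, total, frozenset())


class TestBuildTrajectory:
    def test_complete_records_give_13_values_nothing_imputed(self):
        days = [_day("a", d, d % 5) for d in range(14)]
        traj = build_trajectory(days)
        assert len(traj.values) == 13
        assert traj.imputed_days == frozenset()
        assert traj.values == tuple(float(d % 5) for d in range(1, 14))

    def test_day0_is_dropped(self):
        days = [_day("a", 0, 12)] + [_day("a", d, 1) for d in range(1, 14)]
        traj = build_trajectory(days)
        assert traj.values == tuple([1.0] * 13)

    def test_interior_missing_day_linearly_interpolated(self):
        days = [_day("a", d, 4 if d == 6 else 6 if d == 8 else 2) for d in range(1, 14) if d != 7]
        traj = build_trajectory(days)
        assert traj.values[6] == 5.0  # midpoint of neighbours 4 (day 6) and 6 (day 8)
        assert traj.imputed_days == frozenset({7})

    def test_boundary_missing_days_carry_nearest_value(self):
        days = [_day("a", d, 3) for d in range(4, 12)]
        traj = build_trajectory(days)
        assert traj.values[0] == 3.0 and traj.values[12] == 3.0
        assert traj.imputed_days == frozenset({1, 2, 3, 12, 13})

    def test_fewer_than_two_scored_days_excludes_patient(self):
        with pytest.raises(InsufficientDataError):
            build_trajectory([_day("a", 1, 5)])


class TestDLT:
    def test_tally_counts_true_indicators(self):
        assert dlt_tally([False] * 11) == 0
        assert dlt_tally([True] * 11) == 11
        assert dlt_tally([True] * 4 + [False] * 7) == 4

    @pytest.mark.parametrize("n", [10, 12, 0])
    def test_wrong_indicator_count_rejected(self, n):
        with pytest.raises(ValueError):
            dlt_tally([True] * n)

    def test_record_tally_consistent(self):
        rec = DLTRecord("a", dict(zip(DLT_INDICATOR_NAMES, [True, False] * 5 + [True])))
        assert rec.tally == 6
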