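"""The synthetic cohort generator: archetypes, inverse scoring, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pshtraj.dtw import dtw_distance
from pshtraj.scoring import DEFAULT_RUBRICS, daily_cfs, score_cohort, window_vitals
from pshtraj.simulate import (
    ArchetypeSpec,
    CohortConfig,
    allocate_total,
    generate_cohort,
    make_default_archetypes,
    simulate_covariates,
    simulate_outcomes,
    simulate_trajectories,
    simulate_vitals_for_target_cfs,
    write_cohort,
)


class TestArchetypes:
    def test_curves_length_13_in_range(self):
        for a in make_default_archetypes():
            assert len(a.mean_curve) == 13
            assert all(0 <= v <= 18 for v in a.mean_curve)

    def test_pairwise_dtw_separation_exceeds_5x_noise(self):
        arts = make_default_archetypes(sd_noise=1.5)
        for i in range(len(arts)):
            for j in range(i + 1, len(arts)):
                d = dtw_distance(arts[i].mean_curve, arts[j].mean_curve)
                assert d > 5 * 1.5, (arts[i].name, arts[j].name, d)

    def test_low_curve_below_high_curve_every_day(self):
        arts = {a.name: np.array(a.mean_curve) for a in make_default_archetypes()}
        assert np.all(arts["persistently_low"] < arts["persistently_high"])

    def test_invalid_curve_rejected(self):
        with pytest.raises(ValueError):
            ArchetypeSpec("bad", tuple(np.full(12, 2.0)))


class TestAllocation:
    @pytest.mark.parametrize("total", range(0, 19))
    def test_allocation_sums_and_ranges(self, total):
        sub = allocate_total(total)
        assert sum(sub.values()) == min(total, 16)
        assert all(0 <= sub[c] <= 3 for c in ("HR", "SBP", "RR", "TEMP"))
        assert sub["SWEATING"] in (0, 2) and sub["POSTURING"] in (0, 2)


class TestInverseScoring:
    def test_all_zero_target_keeps_maxima_below_first_cutpoints(self):
        rng = np.random.default_rng(0)
        target = dict.fromkeys(("HR", "SBP", "RR", "TEMP", "SWEATING", "POSTURING"), 0)
        rows, flags = simulate_vitals_for_target_cfs(target, DEFAULT_RUBRICS, rng)
        df = pd.DataFrame(rows)
        for cat, cut in (("HR", 100), ("SBP", 140), ("RR", 18), ("TEMP", 37)):
            assert df[df["parameter"] == cat]["value"].max() < cut
        assert not flags.sweating_mentioned and not flags.posturing_mentioned

    def test_band_2_hr_maximum_falls_in_its_band(self):
        rng = np.random.default_rng(1)
        target = dict.fromkeys(("HR", "SBP", "RR", "TEMP", "SWEATING", "POSTURING"), 0)
        target["HR"] = 2
        rows, _ = simulate_vitals_for_target_cfs(target, DEFAULT_RUBRICS, rng)
        hr_max = pd.DataFrame(rows).query("parameter == 'HR'")["value"].max()
        assert 120 <= hr_max < 140

    def test_at_least_three_samples_per_category_inside_window(self):
        rng = np.random.default_rng(2)
        target = {"HR": 3, "SBP": 1, "RR": 2, "TEMP": 0, "SWEATING": 2, "POSTURING": 0}
        rows, _ = simulate_vitals_for_target_cfs(target, DEFAULT_RUBRICS, rng)
        df = pd.DataFrame(rows)
        assert (df.groupby("parameter").size() >= 3).all()
        day0 = pd.Timestamp("2016-01-01")
        assert df["timestamp"].between(day0, day0 + pd.Timedelta(hours=24)).all()

    def test_invalid_symptom_target_rejected(self):
        with pytest.raises(ValueError):
            simulate_vitals_for_target_cfs(
                {"HR": 0, "SBP": 0, "RR": 0, "TEMP": 0, "SWEATING": 1, "POSTURING": 0},
                DEFAULT_RUBRICS,
                np.random.default_rng(0),
            )

    def test_round_trip_exact_on_random_targets(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            target = {
                "HR": int(rng.integers(0, 4)),
                "SBP": int(rng.integers(0, 4)),
                "RR": int(rng.integers(0, 4)),
                "TEMP": int(rng.integers(0, 4)),
                "SWEATING": int(rng.choice([0, 2])),
                "POSTURING": int(rng.choice([0, 2])),
            }
            rows, flags = simulate_vitals_for_target_cfs(target, DEFAULT_RUBRICS, rng)
            windows = window_vitals(pd.DataFrame(rows), pd.Timestamp("2016-01-01"), 1)
            rec = daily_cfs(windows["p0"][0], flags, DEFAULT_RUBRICS)
            assert dict(rec.sub_scores) == target


class TestTrajectories:
    def test_zero_noise_totals_equal_rounded_curves(self):
        cfg = CohortConfig(n_patients=20, sd_noise=0.0, seed=0)
        labels, totals, _ = simulate_trajectories(cfg, np.random.default_rng(0))
        for p in range(20):
            curve = np.array(cfg.archetypes[labels[p]].mean_curve)
            np.testing.assert_array_equal(totals[p, 1:], np.rint(curve))

    def test_group_means_close_to_archetypes_at_large_n(self):
        cfg = CohortConfig(n_patients=1000, seed=1)
        labels, totals, _ = simulate_trajectories(cfg, np.random.default_rng(1))
        for g, arch in enumerate(cfg.archetypes):
            emp = totals[labels == g, 1:].mean(axis=0)
            assert np.max(np.abs(emp - np.array(arch.mean_curve))) < 0.3

    def test_label_proportions_match_config(self):
        cfg = CohortConfig(n_patients=10000, seed=2)
        labels, _, _ = simulate_trajectories(cfg, np.random.default_rng(2))
        props = np.bincount(labels, minlength=4) / 10000
        assert np.max(np.abs(props - np.array(cfg.group_proportions))) < 0.02


@pytest.fixture(scope="module")
def big():
    cfg = CohortConfig(n_patients=5000, seed=3)
    rng = np.random.default_rng(3)
    labels = rng.choice(4, 5000, p=np.array(cfg.group_proportions))
    cov, types = simulate_covariates(labels, cfg, rng)
    out = simulate_outcomes(labels, cfg, rng)
    return cfg, labels, cov, types, out


class TestCovariatesAndOutcomes:
    def test_group1_age_mean_matches_truncated_normal(self, big):
        cfg, labels, cov, _, _ = big
        a, b = (np.array(cfg.age_bounds) - cfg.age_means[0]) / cfg.age_sd
        expect = stats.truncnorm.mean(a, b, loc=cfg.age_means[0], scale=cfg.age_sd)
        x = cov["age"][labels == 0]
        assert abs(x.mean() - expect) < 4 * cfg.age_sd / np.sqrt(len(x))

    def test_mgcs_in_range_with_group_shifted_medians(self, big):
        _, labels, cov, _, _ = big
        assert cov["mgcs"].between(1, 6).all()
        medians = [cov["mgcs"][labels == g].median() for g in range(4)]
        assert medians[1] > medians[3]

    def test_group4_psh_rate_near_config(self, big):
        cfg, labels, _, _, out = big
        rate = out["psh_case"][labels == 3].mean()
        assert abs(rate - cfg.psh_probs[3]) < 0.02

    def test_dlt_bounded_and_monotone_in_group(self, big):
        _, labels, _, _, out = big
        assert out["dlt"].between(0, 11).all()
        means = [out["dlt"][labels == g].mean() for g in range(4)]
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_equal_psh_probs_give_null_association(self):
        cfg = CohortConfig(n_patients=200, psh_probs=(0.4, 0.4, 0.4, 0.4), seed=0)
        from pshtraj.associations import chi_square_test, crosstab

        sig = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            labels = rng.choice(4, 200, p=np.array(cfg.group_proportions))
            out = simulate_outcomes(labels, cfg, rng)
            p = chi_square_test(crosstab(labels, out["psh_case"])).p_value
            sig += p < 0.05
        assert sig / 60 <= 0.10


class TestGenerateCohort:
    def test_every_patient_in_all_components(self, small_cohort):
        ids = set(small_cohort.true_labels.index)
        assert set(small_cohort.covariates["patient_id"]) == ids
        assert set(small_cohort.outcomes["patient_id"]) == ids
        assert set(small_cohort.vitals["patient_id"]) == ids
        assert set(small_cohort.flags["patient_id"]) == ids

    def test_cohort_round_trip_scores_exactly(self, small_cohort, scored_small):
        daily, _ = scored_small
        cfg = small_cohort.config
        _, totals, _ = simulate_trajectories(cfg, np.random.default_rng(cfg.seed))
        piv = daily.pivot(index="patient_id", columns="day_index", values="total")
        np.testing.assert_array_equal(piv.to_numpy(), totals)

    def test_same_config_twice_is_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_patients=5, seed=9)
        for d in ("a", "b"):
            write_cohort(generate_cohort(cfg), str(tmp_path / d))
        for name in ("vitals.csv", "flags.csv", "covariates.csv", "outcomes.csv", "truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_zero_patients_yield_valid_empty_files(self, tmp_path):
        write_cohort(generate_cohort(CohortConfig(n_patients=0)), str(tmp_path))
        vit = pd.read_csv(tmp_path / "vitals.csv")
        assert list(vit.columns) == ["patient_id", "timestamp", "parameter", "value"]
        assert vit.empty

    def test_csv_round_trip_preserves_scores(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_patients=8, seed=4))
        write_cohort(cohort, str(tmp_path))
        vitals = pd.read_csv(tmp_path / "vitals.csv")
        flags = pd.read_csv(tmp_path / "flags.csv")
        daily_csv, matrix_csv, _ = score_cohort(vitals, flags)
        daily_mem, matrix_mem, _ = score_cohort(cohort.vitals, cohort.flags)
        pd.testing.assert_frame_equal(daily_csv, daily_mem)
        pd.testing.assert_frame_equal(matrix_csv, matrix_mem)

    def test_invalid_config_rejected_before_generation(self):
        with pytest.raises(ValueError):
            CohortConfig(group_proportions=(0.5, 0.5, 0.5, 0.5))
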