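"""Cohort statistics: gut summaries, fold change, KM/LT50, CFU, ddCt, tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import gutquant as gq
from gutquant import summarize_stats as ss
from gutquant.scene_synth import (
    CountSpec,
    PlateSpec,
    QpcrSpec,
    SurvivalSpec,
    generate_plate_image,
)


def _calls(n, gfp=0, small=0, ph3=0, pros=0):
    return pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "size_class": ["small"] * small + ["large"] * (n - small),
            "gfp": [1] * gfp + [0] * (n - gfp),
            "ph3": [1] * ph3 + [0] * (n - ph3),
            "pros": [1] * pros + [0] * (n - pros),
        }
    )


class TestSummarizeGut:
    def test_counts_and_proportions(self):
        s = ss.summarize_gut(_calls(10, gfp=9, small=4), "g1")
        assert s["total_cells"] == 10
        assert s["prop_gfp"] == pytest.approx(0.9)
        assert s["n_small"] + s["n_large"] == 10
        assert s["prop_small"] + s["prop_large"] == pytest.approx(1.0)

    def test_all_small_zero_large_proportion(self):
        s = ss.summarize_gut(_calls(6, small=6))
        assert s["prop_large"] == 0.0

    def test_double_positive_bounded(self):
        s = ss.summarize_gut(_calls(10, gfp=5, pros=3))
        assert s["n_gfp_and_pros"] <= min(s["n_gfp"], s["n_pros"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ss.summarize_gut(_calls(0))


class TestMitoticIndex:
    def test_mean_of_constant_counts(self):
        df = pd.DataFrame({"group": ["a"] * 3, "count": [2, 2, 2]})
        out = ss.mitotic_index(df)
        assert out.loc["a", "mean"] == 2.0 and out.loc["a", "sd"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ss.mitotic_index(pd.DataFrame({"group": [], "count": []}))

    def test_generator_group_means_recovered(self):
        table = gq.generate_count_cohort(CountSpec(n_per_group=30, seed=9))
        out = ss.mitotic_index(table)
        assert out.loc["control", "mean"] == pytest.approx(2.0, rel=0.15)
        assert out.loc["treated", "mean"] == pytest.approx(20.0, rel=0.15)


class TestFoldChange:
    def test_identical_groups_give_one(self):
        v = np.array([1.0, 2.0, 3.0])
        assert ss.fold_change(v, v).fold == pytest.approx(1.0)

    def test_exact_threefold(self):
        c = np.array([1.0, 2.0, 3.0])
        res = ss.fold_change(3 * c, c)
        assert res.fold == pytest.approx(3.0)
        assert res.ci_low <= 3.0 <= res.ci_high

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        t, c = rng.exponential(5, 40), rng.exponential(1, 40)
        assert ss.fold_change(7 * t, 7 * c).fold == pytest.approx(ss.fold_change(t, c).fold)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            ss.fold_change(np.ones(3), np.zeros(3))

    def test_infection_preset_recovery(self):
        table = gq.generate_count_cohort(
            CountSpec(n_per_group=10_000, baseline_mean=2.0, fold=10.0, seed=1)
        )
        t = table.loc[table.group == "treated", "count"].to_numpy()
        c = table.loc[table.group == "control", "count"].to_numpy()
        res = ss.fold_change(t, c, n_boot=200, seed=0)
        assert 9.0 <= res.fold <= 11.0


class TestKaplanMeierLT50:
    def test_hand_computed_steps(self):
        # times 1,2,3,4 all events: S = .75, .50, .25, 0; S first reaches
        # 0.5 at t=2, interpolated from (1, .75) -> LT50 = 2, within [2, 3]
        df = pd.DataFrame({"group": "a", "time": [1, 2, 3, 4], "event": 1})
        out = ss.km_lt50(df)
        assert out.loc["a", "defined"]
        assert 2.0 <= out.loc["a", "lt50"] <= 3.0
        assert out.loc["a", "lt50"] == pytest.approx(2.0)

    def test_single_event(self):
        df = pd.DataFrame({"group": "a", "time": [5.0], "event": [1]})
        assert ss.km_lt50(df).loc["a", "lt50"] == 5.0

    def test_all_censored_flagged_undefined(self):
        df = pd.DataFrame({"group": "a", "time": [5.0, 6.0], "event": [0, 0]})
        out = ss.km_lt50(df)
        assert not out.loc["a", "defined"]
        assert np.isnan(out.loc["a", "lt50"])

    def test_no_censoring_matches_sample_median_bracket(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.weibull(3, 100) * 20)
        df = pd.DataFrame({"group": "a", "time": t, "event": 1})
        lt50 = ss.km_lt50(df).loc["a", "lt50"]
        assert t[48] <= lt50 <= t[51]

    def test_curve_non_increasing(self):
        rng = np.random.default_rng(3)
        t = rng.weibull(2, 200) * 10
        e = rng.integers(0, 2, 200)
        e[0] = 1
        step_t, step_s = ss._km_steps(t, e)
        assert np.all(np.diff(step_s) < 0)
        assert np.all(np.diff(step_t) > 0)

    def test_oral_control_preset_recovery(self):
        cohort = gq.generate_survival_cohort(
            gq.survival_preset("oral_control", n=2000, seed=5), group="oral_control"
        )
        lt50 = ss.km_lt50(cohort).loc["oral_control", "lt50"]
        assert lt50 == pytest.approx(23.3, rel=0.05)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        df = pd.DataFrame(
            {"group": ["a"] * 5 + ["b"] * 5, "time": np.tile(t, 2), "event": 1}
        )
        res = ss.logrank(df, "a", "b")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_doubled_times_highly_significant(self):
        rng = np.random.default_rng(4)
        t = rng.weibull(3, 300) * 10
        df = pd.DataFrame(
            {
                "group": ["a"] * 300 + ["b"] * 300,
                "time": np.concatenate([t, 2 * t]),
                "event": 1,
            }
        )
        assert ss.logrank(df, "a", "b").p_value < 1e-4

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"group": ["a"] * 3, "time": [1.0, 2.0, 3.0], "event": 1})
        with pytest.raises(ValueError):
            ss.logrank(df, "a", "b")


class TestColonyCounting:
    def test_blank_plate_counts_zero(self):
        assert ss.count_colonies(np.full((64, 64), 10.0)).count == 0

    def test_preset_plate_recovered(self):
        img, truth = generate_plate_image(PlateSpec(n_colonies=120, seed=3))
        res = ss.count_colonies(img, min_area_px=5)
        assert abs(res.count - truth.n_colonies) <= 2

    def test_touching_colonies_merge_and_flag(self):
        img = np.zeros((80, 80))
        yy, xx = np.ogrid[:80, :80]
        for cy, cx in [(20, 20), (60, 20), (40, 56), (40, 64)]:  # last two touch
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 25] = 100.0
        res = ss.count_colonies(img, threshold_method=50.0)
        assert res.count == 3
        assert len(res.area_outliers) == 1


class TestCfu:
    def test_hand_arithmetic(self):
        # 100 colonies, 1:100 dilution, 200 ul of 1 ml plated, 5 guts:
        # CFU/gut = 100 * 100 / 0.2 / 5 = 10^4
        res = ss.cfu_log10([100], 100.0, 200.0, 1000.0, 5)
        assert res.cfu_per_gut == pytest.approx(1e4)
        assert res.log10_cfu == pytest.approx(4.0)

    def test_technical_replicates_averaged_before_scaling(self):
        res = ss.cfu_log10([90, 100, 110], 100.0, 200.0, 1000.0, 5)
        assert res.cfu_per_gut == pytest.approx(1e4)

    def test_zero_counts_below_detection_not_minus_inf(self):
        res = ss.cfu_log10([0, 0, 0], 100.0, 200.0, 1000.0, 5)
        assert res.below_detection
        assert np.isnan(res.log10_cfu)
        assert np.isfinite(res.detection_limit_log10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ss.cfu_log10([10], 0.0, 200.0)
        with pytest.raises(ValueError):
            ss.cfu_log10([-1], 100.0, 200.0)


class TestDdct:
    def _table(self, target_shift=0.0):
        rows = []
        for cond, shift in [("cal", 0.0), ("exp", target_shift)]:
            for rep in (1, 2, 3):
                rows.append(("tgt", cond, rep, 24.0 + shift))
                rows.append(("RpL32", cond, rep, 16.0))
                rows.append(("Gapdh1", cond, rep, 18.0))
        return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])

    def test_calibrator_expression_is_one(self):
        res = ss.ddct(self._table(), "tgt", ("RpL32", "Gapdh1"), "cal")
        assert res.loc[res.condition == "cal", "rel_expr"].item() == pytest.approx(1.0)

    def test_two_cycles_lower_is_fourfold(self):
        res = ss.ddct(self._table(target_shift=-2.0), "tgt", ("RpL32", "Gapdh1"), "cal")
        assert res.loc[res.condition == "exp", "rel_expr"].item() == pytest.approx(4.0)

    def test_missing_reference_gene_rejected(self):
        table = self._table()
        with pytest.raises(ValueError):
            ss.ddct(table[table.gene != "Gapdh1"], "tgt", ("RpL32", "Gapdh1"), "cal")


class TestOdConversion:
    def test_calibration_point_exact(self):
        assert ss.od_to_density(3.0) == 5e9

    def test_linearity(self):
        assert ss.od_to_density(0.0) == 0.0
        assert ss.od_to_density(1.5) == pytest.approx(2.5e9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ss.od_to_density(-0.1)


def exact_mann_whitney_p(x, y):
    """Exhaustive permutation enumeration of the two-sided Mann-Whitney p."""
    pooled = np.concatenate([x, y])
    n = len(x)
    obs = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
    mu = len(x) * len(y) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        u = sps.mannwhitneyu(pooled[mask], pooled[~mask], alternative="two-sided").statistic
        total += 1
        if abs(u - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total


class TestCompareGroups:
    def test_t_statistic_zero_for_identical_groups(self):
        res = ss.compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, "t_unpaired")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_mann_whitney_identical_groups_p_one(self):
        res = ss.compare_groups({"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4, 5]}, "mann_whitney")
        assert res.p_value > 0.99

    def test_mann_whitney_matches_exact_enumeration(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 5)
        y = rng.normal(1, 1, 5)
        res = ss.compare_groups({"x": x, "y": y}, "mann_whitney")
        assert res.p_value == pytest.approx(exact_mann_whitney_p(x, y), abs=1e-9)

    def test_anova_accepts_three_groups(self):
        rng = np.random.default_rng(12)
        groups = {k: rng.normal(0, 1, 10) for k in "abc"}
        res = ss.compare_groups(groups, "anova_oneway")
        assert 0.0 <= res.p_value <= 1.0

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            ss.compare_groups({"a": [1.0], "b": [1.0, 2.0]}, "t_unpaired")
        with pytest.raises(ValueError):
            ss.compare_groups({"a": [1.0, 2.0]}, "anova_oneway")

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            ss.compare_groups({"a": [1.0, 2.0], "b": [3.0, 4.0]}, "wilcoxon")
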