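"""Exclusion filter, damage/excess rates, test battery and power analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from petdsb.cohort import FOCI_CLASS_COLUMNS, REFERENCE_FOCUS_SPECTRUM_PCT
from petdsb.stats import (
    apply_filter,
    damage_rate,
    damage_rates_table,
    excess_rates,
    mean_foci_per_cell,
    min_n_for_power,
    power_simulation,
    run_test_battery,
)


def slide_row(classes, gt5=0, vid="v1", arm="SA1", sp="SP1", it=60, slide=1):
    assert len(classes) == 6
    return {
        "volunteer_id": vid,
        "arm": arm,
        "sampling_point": sp,
        "incubation_min": it,
        "slide_id": slide,
        "n_cells_scanned": int(sum(classes)) + gt5,
        **{c: int(v) for c, v in zip(FOCI_CLASS_COLUMNS, classes)},
        "n_excluded_gt5": gt5,
    }


def spectrum_pseudo_slide(scale=1000, **kw):
    # published study-wide spectrum as integer counts per 100*scale cells
    counts = [round(p * scale) for p in REFERENCE_FOCUS_SPECTRUM_PCT]
    return slide_row(counts[:6], gt5=counts[6], **kw)


class TestApplyFilter:
    def test_toy_slide_hand_count(self):
        table = pd.DataFrame([slide_row([990, 5, 2, 1, 1, 0], gt5=1)])
        filtered = apply_filter(table)
        assert int(filtered["n_cells_scanned"].iloc[0]) == 999
        rec = damage_rate(filtered, "v1", "SP1", 60)
        assert rec["n_cells_retained"] == 999
        assert rec["n_cells_with_focus"] == 9

    def test_no_excluded_cells_unchanged(self):
        table = pd.DataFrame([slide_row([990, 10, 0, 0, 0, 0], gt5=0)])
        pd.testing.assert_frame_equal(apply_filter(table), table)

    @given(
        classes=st.lists(st.integers(0, 5000), min_size=6, max_size=6),
        gt5=st.integers(0, 50),
    )
    def test_idempotent(self, classes, gt5):
        if sum(classes) == 0:
            classes[0] = 1
        table = pd.DataFrame([slide_row(classes, gt5=gt5)])
        once = apply_filter(table)
        pd.testing.assert_frame_equal(apply_filter(once), once)


class TestDamageRate:
    def test_all_zero_cells(self):
        table = pd.DataFrame([slide_row([1500, 0, 0, 0, 0, 0])])
        assert damage_rate(apply_filter(table), "v1", "SP1", 60)["rate_pct"] == 0.0

    def test_published_spectrum_rate(self):
        filtered = apply_filter(pd.DataFrame([spectrum_pseudo_slide()]))
        rec = damage_rate(filtered, "v1", "SP1", 60)
        assert rec["rate_pct"] == pytest.approx(1.416, abs=0.001)

    def test_invariant_to_slide_partitioning(self):
        pooled = pd.DataFrame([slide_row([4000, 50, 6, 1, 0, 0], gt5=3)])
        split = pd.DataFrame(
            [
                slide_row([1000, 30, 5, 1, 0, 0], gt5=2, slide=1),
                slide_row([3000, 20, 1, 0, 0, 0], gt5=1, slide=2),
            ]
        )
        ra = damage_rate(apply_filter(pooled), "v1", "SP1", 60)
        rb = damage_rate(apply_filter(split), "v1", "SP1", 60)
        assert ra["rate_pct"] == pytest.approx(rb["rate_pct"], rel=1e-12)
        assert ra["n_cells_retained"] == rb["n_cells_retained"]

    def test_duplicating_slides_leaves_rate_unchanged(self):
        one = pd.DataFrame([slide_row([2000, 25, 3, 0, 0, 0])])
        two = pd.DataFrame([slide_row([2000, 25, 3, 0, 0, 0], slide=1),
                            slide_row([2000, 25, 3, 0, 0, 0], slide=2)])
        ra = damage_rate(apply_filter(one), "v1", "SP1", 60)
        rb = damage_rate(apply_filter(two), "v1", "SP1", 60)
        assert ra["rate_pct"] == rb["rate_pct"]

    def test_zero_retained_cells_error(self):
        table = pd.DataFrame([slide_row([0, 0, 0, 0, 0, 0], gt5=10)])
        with pytest.raises(ValueError):
            damage_rate(apply_filter(table), "v1", "SP1", 60)


class TestMeanFociPerCell:
    def test_published_spectrum_gives_0016(self):
        filtered = apply_filter(pd.DataFrame([spectrum_pseudo_slide()]))
        assert round(mean_foci_per_cell(filtered), 3) == 0.016

    def test_all_zeros(self):
        assert mean_foci_per_cell(np.array([100, 0, 0, 0, 0, 0])) == 0.0

    def test_singleton_three_foci(self):
        assert mean_foci_per_cell(np.array([0, 0, 0, 1, 0, 0])) == 3.0

    def test_zero_retained_rejected(self):
        with pytest.raises(ValueError):
            mean_foci_per_cell(np.zeros(6))


class TestExcessRates:
    def rates_frame(self, rows):
        return pd.DataFrame(
            [
                {"volunteer_id": v, "arm": a, "sampling_point": sp, "incubation_min": it,
                 "n_cells_retained": 10_000, "n_cells_with_focus": int(100 * r), "rate_pct": r}
                for v, a, sp, it, r in rows
            ]
        )

    def test_identical_pre_post_zero(self):
        rates = self.rates_frame([("v1", "SA1", "SP1", 60, 1.0), ("v1", "SA1", "SP3", 60, 1.0)])
        ex = excess_rates(rates)
        assert ex["excess_pct"].iloc[0] == 0.0

    def test_stated_pair_arithmetic(self):
        rates = self.rates_frame([("v1", "SA1", "SP1", 60, 1.0), ("v1", "SA1", "SP3", 60, 1.31)])
        ex = excess_rates(rates)
        assert ex["excess_pct"].iloc[0] == pytest.approx(0.31)
        assert ex["relative_excess_pct"].iloc[0] == pytest.approx(31.0)

    def test_missing_benchmark_reported_as_skipped(self):
        rates = self.rates_frame([("v1", "SA1", "SP3", 60, 1.2)])
        ex = excess_rates(rates)
        assert bool(ex["skipped"].iloc[0])
        assert np.isnan(ex["excess_pct"].iloc[0])

    def test_alternative_sp2_benchmark(self):
        rates = self.rates_frame(
            [("v1", "SA1", "SP2", 60, 1.1), ("v1", "SA1", "SP3", 60, 1.43)]
        )
        ex = excess_rates(rates, pre=("SP2", 60))
        assert ex["excess_pct"].iloc[0] == pytest.approx(0.33)
        assert "SP2" in ex["contrast"].iloc[0]


def kruskal_permutation_p(groups, n_perm=20_000, seed=0):
    """Brute-force permutation p-value for the Kruskal-Wallis statistic."""
    from scipy.stats import kruskal

    obs = kruskal(*groups).statistic
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        if kruskal(*parts).statistic >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


class TestRunTestBattery:
    def synthetic_rates(self, shift_sa3=0.0, seed=0, n=10):
        rng = np.random.default_rng(seed)
        rows = []
        for arm, n_arm in (("SA1", n), ("SA2", n), ("SA3", n)):
            for i in range(n_arm):
                vid = f"{arm}-{i}"
                bg = rng.normal(1.0, 0.2)
                for sp, it in [("SP1", 0), ("SP1", 60), ("SP3", 0), ("SP3", 15),
                               ("SP3", 30), ("SP3", 45), ("SP3", 60)]:
                    r = bg + rng.normal(0, 0.05)
                    if arm == "SA3" and sp == "SP3":
                        r += shift_sa3
                    rows.append({"volunteer_id": vid, "arm": arm, "sampling_point": sp,
                                 "incubation_min": it, "n_cells_retained": 10_000,
                                 "n_cells_with_focus": 100, "rate_pct": r})
        return pd.DataFrame(rows)

    def test_null_data_mostly_insignificant(self):
        res = run_test_battery(self.synthetic_rates(shift_sa3=0.0, seed=4))
        main = res[~res["test"].str.startswith(("dunn", "tukey"))]
        assert (~main["significant"]).mean() > 0.7
        kw = res[res["test"].str.startswith("kruskal")].iloc[0]
        assert kw["p_value"] > 0.05

    def test_shifted_group_flagged_by_kw_and_dunn(self):
        res = run_test_battery(self.synthetic_rates(shift_sa3=1.0, seed=5))
        kw = res[res["test"].str.startswith("kruskal")].iloc[0]
        assert kw["significant"]
        dunn = res[res["test"].str.startswith("dunn")]
        sig = set(dunn[dunn["significant"]]["groups"])
        assert sig and all("SA3" in g for g in sig)

    def test_kw_p_matches_permutation_oracle_small_sample(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(0, 1, 5), rng.normal(0, 1, 5), rng.normal(1.8, 1, 5)]
        from scipy.stats import kruskal

        p_asym = kruskal(*groups).pvalue
        p_perm = kruskal_permutation_p(groups)
        assert p_asym == pytest.approx(p_perm, abs=0.02)

    def test_brown_forsythe_detects_variance_inflation(self):
        from scipy.stats import levene

        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 32)
        b = rng.normal(0, np.sqrt(7.56), 32)
        stat, p = levene(a, b, center="median")
        assert p < 0.05

    def test_insufficient_groups_marked_not_computable(self):
        rates = self.synthetic_rates(seed=6, n=3)
        res = run_test_battery(rates)
        assert (res["test"].str.startswith("wilcoxon[SP3")).any()
        assert res[res["test"].str.startswith("wilcoxon[SP3")]["p_value"].isna().all()


class TestPowerSimulation:
    def test_size_under_null(self):
        power, se = power_simulation(10, effect_sd_multiple=0.0, n_reps=5000, seed=13)
        assert abs(power - 0.05) < 3 * max(se, np.sqrt(0.05 * 0.95 / 5000))

    def test_huge_effect_near_one(self):
        power, _ = power_simulation(10, effect_sd_multiple=8.0, n_reps=1000, seed=13)
        assert power > 0.99

    def test_design_power_at_n10(self):
        power, _ = power_simulation(10, effect_sd_multiple=1.5, n_reps=5000, seed=13)
        assert power >= 0.80

    def test_matches_scipy_kruskal_on_sample(self):
        # vectorised H statistic agrees with scipy on random draws
        from scipy.stats import kruskal

        from petdsb.stats import _kruskal_wallis_h

        rng = np.random.default_rng(3)
        data = rng.standard_normal((20, 3, 7))
        ours = _kruskal_wallis_h(data)
        theirs = np.array([kruskal(*rep).statistic for rep in data])
        np.testing.assert_allclose(ours, theirs, rtol=1e-9)

    def test_min_n_monotone_in_target(self):
        n80 = min_n_for_power(0.80, n_reps=1500, seed=21)
        n90 = min_n_for_power(0.90, n_reps=1500, seed=21)
        assert n90 >= n80

    def test_min_n_is_minimal_for_target(self):
        # contract: returned n attains the target and n-1 does not (same seed)
        n = min_n_for_power(0.04, effect_sd_multiple=0.0, n_reps=1500, seed=2)
        p_at, _ = power_simulation(n, 0.0, n_reps=1500, seed=2)
        assert p_at >= 0.04
        if n > 2:
            p_below, _ = power_simulation(n - 1, 0.0, n_reps=1500, seed=2)
            assert p_below < 0.04

    def test_variance_reading_needs_more_participants(self):
        n_sd = min_n_for_power(0.80, 1.5, n_reps=2000, seed=22)
        n_var = min_n_for_power(0.80, 1.5, n_reps=2000, seed=22, effect_on_variance_scale=True)
        assert n_sd <= 10 <= n_var <= 16


class TestEndToEndPattern:
    def test_study_reproduces_qualitative_findings(self, study_results):
        # radiotracer arms show positive median excess, the field-only arm none
        excess = study_results["excess"]
        med = excess.groupby("arm")["excess_pct"].median()
        assert med["SA1"] > 0.1 and med["SA3"] > 0.1
        assert abs(med["SA2"]) < 0.15

    def test_battery_on_synthetic_study(self, study_results):
        tests = study_results["tests"]
        by_name = {t: row for t, row in tests.set_index("test").iterrows()}
        assert by_name["wilcoxon[SP3/IT60 vs SP1/IT60, SA2]"]["p_value"] > 0.05
        kw = by_name["kruskal_wallis[excess by arm]"]
        assert np.isfinite(kw["p_value"])

    def test_rates_table_complete(self, default_study, study_results):
        rates = study_results["rates"]
        # every volunteer contributes the full condition plan
        n_conditions = rates.groupby("volunteer_id").size()
        assert set(n_conditions.unique()) == {7, 8}  # 7 for SA2 (no SP2), 8 otherwise
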