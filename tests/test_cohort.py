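"""Synthetic cohort, foci-count model calibration and study generator."""

import numpy as np
import pandas as pd
import pytest

from petdsb.cohort import (
    FOCI_CLASS_COLUMNS,
    REFERENCE_FOCUS_SPECTRUM_PCT,
    SPECTRUM_MATCHING_RATE_PCT,
    ArmSpec,
    CohortParams,
    FociGeneratorParams,
    condition_plan,
    focus_class_probabilities,
    generate_cohort,
    generate_foci_table,
    generate_study,
)
from petdsb.dosimetry import DoseReport


class TestGenerateCohort:
    def test_allocation_matches_design(self):
        cohort = generate_cohort(seed=0)
        assert len(cohort) == 32
        by_arm = {a: [v for v in cohort if v.arm == a] for a in ("SA1", "SA2", "SA3")}
        assert [len(by_arm[a]) for a in ("SA1", "SA2", "SA3")] == [10, 12, 10]
        assert sum(v.sex == "M" for v in by_arm["SA2"]) == 4
        assert all(v.administered_activity_MBq is None for v in by_arm["SA2"])
        assert all(v.administered_activity_MBq > 0 for v in by_arm["SA1"] + by_arm["SA3"])

    def test_anthropometry_within_published_ranges(self):
        cohort = generate_cohort(seed=1)
        sa1 = [v for v in cohort if v.arm == "SA1"]
        assert all(63.0 <= v.weight_kg <= 100.0 for v in sa1)
        assert all(22.0 <= v.age <= 32.0 for v in sa1)
        bmi = [v.weight_kg / v.height_m**2 for v in sa1]
        assert all(20.3 <= b <= 33.4 for b in bmi)

    def test_mean_sa1_weight_recovers_published_mean(self):
        rng = np.random.default_rng(12)
        weights = []
        for _ in range(1000):
            weights.extend(v.weight_kg for v in generate_cohort(rng) if v.arm == "SA1")
        weights = np.asarray(weights)
        se = weights.std(ddof=1) / np.sqrt(weights.size)
        assert abs(weights.mean() - 77.0) < 3 * se

    def test_activity_tracks_weight(self):
        cohort = generate_cohort(seed=2)
        for v in cohort:
            if v.administered_activity_MBq is not None:
                assert v.administered_activity_MBq / v.weight_kg == pytest.approx(4.3, rel=0.25)


class TestFocusCountModel:
    def test_degenerate_rate_always_zero(self, rng):
        from petdsb.cohort import sample_cell_focus_count

        p = FociGeneratorParams(artifact_prob=0.0)
        counts = sample_cell_focus_count(p, 0.0, rng, size=10_000)
        assert np.all(counts == 0)

    def test_class_probabilities_sum_to_one(self):
        p = FociGeneratorParams()
        for rate in (0.0, 0.5, 1.04, 1.39, 5.0, 100.0):
            probs = focus_class_probabilities(p, rate)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(probs >= 0)

    def test_spectrum_calibration_matches_published_classes(self, rng):
        # 1e7 cells at the spectrum-matching rate: classes 0, 1, 2 within 3 SE
        from petdsb.cohort import sample_cell_focus_count

        p = FociGeneratorParams()
        n = 10_000_000
        counts = sample_cell_focus_count(p, SPECTRUM_MATCHING_RATE_PCT, rng, size=n)
        for k in range(3):
            frac = float(np.mean(counts == k))
            target = REFERENCE_FOCUS_SPECTRUM_PCT[k] / 100.0
            se = np.sqrt(target * (1 - target) / n)
            assert abs(frac - target) < 3 * se, f"class {k}: {frac} vs {target}"

    def test_probability_of_any_focus_tracks_condition_rate(self, rng):
        from petdsb.cohort import sample_cell_focus_count

        p = FociGeneratorParams()
        rate = 1.04
        n = 1_000_000
        counts = sample_cell_focus_count(p, rate, rng, size=n)
        frac = float(np.mean(counts >= 1))
        model = 1.0 - focus_class_probabilities(p, rate)[0]
        se = np.sqrt(model * (1 - model) / n)
        assert abs(frac - model) < 3 * se
        # artifact override adds at most artifact_prob to the nominal rate
        assert abs(model - rate / 100.0) < p.artifact_prob

    def test_per_cell_sampler_consistent_with_multinomial_probabilities(self, rng):
        from petdsb.cohort import _slide_class_counts, sample_cell_focus_count

        p = FociGeneratorParams(artifact_prob=0.01)  # exaggerate tail for power
        rate, n = 5.0, 400_000
        counts = sample_cell_focus_count(p, rate, rng, size=n)
        observed = np.array([(counts == k).sum() for k in range(6)] + [(counts > 5).sum()])
        expected = focus_class_probabilities(p, rate) * n
        chi2 = float(((observed - expected) ** 2 / np.maximum(expected, 1e-9)).sum())
        from scipy.stats import chi2 as chi2_dist

        assert chi2_dist.sf(chi2, df=6) > 0.001


class TestGenerateFociTable:
    def dose_zeros(self):
        return DoseReport.zeros("v")

    def test_schema_and_invariants(self, rng):
        from helpers import make_volunteer

        vol = make_volunteer(arm="SA2", activity=None)
        table = generate_foci_table(vol, None, rng=rng)
        class_sum = table[FOCI_CLASS_COLUMNS].sum(axis=1) + table["n_excluded_gt5"]
        assert (class_sum == table["n_cells_scanned"]).all()
        assert table["n_cells_scanned"].min() >= 1002
        slides = table.groupby(["sampling_point", "incubation_min"])["slide_id"].max()
        assert slides.between(1, 10).all()

    def test_condition_plan_by_arm(self):
        assert ("SP2", 60) in condition_plan("SA1")
        assert ("SP2", 60) not in condition_plan("SA2")
        for arm in ("SA1", "SA2", "SA3"):
            assert ("SP1", 0) in condition_plan(arm)
            assert sum(sp == "SP3" for sp, _ in condition_plan(arm)) == 5

    def test_fdg_volunteer_requires_dose_report(self, rng):
        from helpers import make_volunteer

        with pytest.raises(ValueError):
            generate_foci_table(make_volunteer(), None, rng=rng)

    def test_null_generator_shares_background_across_conditions(self):
        # no dose response, no venipuncture effect: all conditions equal in expectation
        from helpers import make_volunteer

        p = FociGeneratorParams(
            dose_slope_pct_per_mGy=0.0,
            venipuncture_excess_pct=0.0,
            venipuncture_variance_ratio=1.0,
            background_rate_sd_pct=0.0,
            cells_per_slide_median=30_000,
            slide_count_probs=(0, 0, 0, 0, 0, 0, 0, 0, 0, 1.0),
        )
        vol = make_volunteer(arm="SA2", activity=None)
        table = generate_foci_table(vol, None, p, rng=np.random.default_rng(8))
        with_focus = table[FOCI_CLASS_COLUMNS[1:]].sum(axis=1) + table["n_excluded_gt5"]
        rates = (
            pd.DataFrame({"r": with_focus / table["n_cells_scanned"],
                          "sp": table["sampling_point"], "it": table["incubation_min"]})
            .groupby(["sp", "it"])["r"].mean()
        )
        n_per_cond = 300_000.0
        se = np.sqrt(0.0104 * (1 - 0.0104) / n_per_cond)
        assert np.all(np.abs(rates.to_numpy() - 0.0104) < 4 * se)

    def test_sa2_incubation_series_flat(self, rng):
        # SA2 post-exposure samples carry no dose excess at any incubation time
        from helpers import make_volunteer

        p = FociGeneratorParams(background_rate_sd_pct=0.0, cells_per_slide_median=50_000,
                                slide_count_probs=(0, 0, 0, 0, 0, 0, 0, 0, 0, 1.0))
        vol = make_volunteer(arm="SA2", activity=None)
        table = generate_foci_table(vol, None, p, rng=rng)
        sp3 = table[table["sampling_point"] == "SP3"]
        with_focus = sp3[FOCI_CLASS_COLUMNS[1:]].sum(axis=1) + sp3["n_excluded_gt5"]
        rate_by_it = (with_focus / sp3["n_cells_scanned"]).groupby(sp3["incubation_min"]).mean()
        se = np.sqrt(0.0104 * 0.9896 / 500_000.0)
        assert rate_by_it.max() - rate_by_it.min() < 6 * se


class TestGenerateStudy:
    def test_deterministic_under_fixed_seed(self):
        a = generate_study(seed=5, saf_histories=5000)
        b = generate_study(seed=5, saf_histories=5000)
        pd.testing.assert_frame_equal(a.foci, b.foci)
        assert a.dose_reports == b.dose_reports
        for vid in a.tacs:
            np.testing.assert_array_equal(a.tacs[vid].conc_kBq_per_ml, b.tacs[vid].conc_kBq_per_ml)

    def test_different_seeds_differ(self):
        a = generate_study(seed=5, saf_histories=5000)
        b = generate_study(seed=6, saf_histories=5000)
        assert not a.foci.equals(b.foci)

    def test_dataset_passes_table_invariants(self, default_study):
        foci = default_study.foci
        class_sum = foci[FOCI_CLASS_COLUMNS].sum(axis=1) + foci["n_excluded_gt5"]
        assert (class_sum == foci["n_cells_scanned"]).all()
        assert foci["n_cells_scanned"].min() >= 1002
        assert (foci[FOCI_CLASS_COLUMNS] >= 0).all().all()
        assert set(foci["arm"]) == {"SA1", "SA2", "SA3"}

    def test_fdg_doses_present_and_positive(self, default_study):
        for vol in default_study.volunteers:
            rep = default_study.dose_reports[vol.id]
            if vol.is_fdg_exposed:
                assert rep.D_invivo_mGy > 0
                assert rep.D_invitro_mGy[60] > 0
            else:
                assert rep.D_invivo_mGy == 0


class TestParameterRecovery:
    def test_dose_slope_recovered_at_oversize(self, oversize_recovery):
        # 240 FDG volunteers: median excess ~ beta_D * median total dose
        med_excess, expected = oversize_recovery
        assert med_excess == pytest.approx(expected, rel=0.10)
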