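import numpy as np
import pytest

from punctakit import (
    AnalysisConfig,
    CropDataset,
    DetectionParams,
    RestrictionParams,
    confusion_rates,
    peakfinder_1d,
    sensitivity_sweep,
)
from punctakit.synthetic import SceneSpec, endogenous_like, generate_scene
from punctakit.validation import collapse_columns, sensitivity_grid, welch_anova_p


class TestConfusionRates:
    def test_perfect_prediction(self, rng):
        truth = rng.random((10, 30)) < 0.2
        if not truth.any() or truth.all():
            pytest.skip("degenerate draw")
        r = confusion_rates(truth, truth)
        assert (r.tpr, r.tnr, r.balanced_accuracy) == (1.0, 1.0, 1.0)

    def test_complement_prediction(self, rng):
        truth = rng.random((10, 30)) < 0.2
        if not truth.any() or truth.all():
            pytest.skip("degenerate draw")
        r = confusion_rates(~truth, truth)
        assert (r.tpr, r.tnr, r.balanced_accuracy) == (0.0, 0.0, 0.0)

    def test_hand_counted_example(self):
        # 4x4: TP=2, FN=2, TN=10, FP=2
        truth = np.zeros((4, 4), dtype=bool)
        truth[0, 0:4] = True
        pred = np.zeros((4, 4), dtype=bool)
        pred[0, 0:2] = True  # 2 TP, misses truth[0,2:4]
        pred[1, 0:2] = True  # 2 FP
        r = confusion_rates(pred, truth)
        assert r.tpr == pytest.approx(0.5)
        assert r.tnr == pytest.approx(10 / 12)
        assert r.balanced_accuracy == pytest.approx((0.5 + 10 / 12) / 2)

    def test_ba_identity_exact(self, rng):
        for _ in range(20):
            truth = rng.random((8, 25)) < rng.uniform(0.1, 0.9)
            pred = rng.random((8, 25)) < rng.uniform(0.1, 0.9)
            if not truth.any() or truth.all():
                continue
            r = confusion_rates(pred, truth)
            assert r.balanced_accuracy == (r.tpr + r.tnr) / 2.0

    def test_column_mode_equals_pixel_mode_on_collapsed(self, rng):
        truth = rng.random((10, 40)) < 0.1
        pred = rng.random((10, 40)) < 0.1
        ct, cp = collapse_columns(truth), collapse_columns(pred)
        if not ct.any() or ct.all():
            pytest.skip("degenerate draw")
        a = confusion_rates(pred, truth, mode="column1d")
        b = confusion_rates(cp, ct, mode="pixel2d")
        assert (a.tpr, a.tnr) == (b.tpr, b.tnr)

    def test_union_collapse_superset(self, rng):
        pred = rng.random((10, 40)) < 0.1
        truth = rng.random((10, 40)) < 0.1
        both = collapse_columns(pred | truth)
        assert (collapse_columns(pred) & ~both).sum() == 0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="TPR undefined"):
            confusion_rates(np.zeros((4, 4), bool), np.zeros((4, 4), bool))

    def test_full_truth_rejected(self):
        with pytest.raises(ValueError, match="TNR undefined"):
            confusion_rates(np.ones((4, 4), bool), np.ones((4, 4), bool))


class TestPeakfinder:
    def triangular(self, apex_col, apex_height, width, n=100, base=10.0):
        profile = np.full(n, base)
        for d in range(width + 1):
            h = apex_height * (1 - d / (width + 1))
            if apex_col - d >= 0:
                profile[apex_col - d] = max(profile[apex_col - d], base + h)
            if apex_col + d < n:
                profile[apex_col + d] = max(profile[apex_col + d], base + h)
        return profile

    def test_single_bump_found_at_apex(self):
        prof = self.triangular(40, 100.0, 5)
        peaks = peakfinder_1d(prof[None, :], min_prominence=50.0, max_width_cols=20.0)
        assert len(peaks.peaks) == 1
        assert peaks.peaks[0].position == 40

    def test_two_bumps_with_deep_valley(self):
        prof = self.triangular(30, 100.0, 4) + self.triangular(42, 100.0, 4) - 10.0
        peaks = peakfinder_1d(prof[None, :], min_prominence=30.0, max_width_cols=15.0)
        assert [p.position for p in peaks.peaks] == [30, 42]

    def test_height_floor_excludes_dim_bump(self):
        prof = self.triangular(40, 30.0, 5, base=100.0)
        kept = peakfinder_1d(prof[None, :], 5.0, 20.0, noise_to_signal_ratio=0.0)
        assert len(kept.peaks) == 1
        dropped = peakfinder_1d(prof[None, :], 5.0, 20.0, noise_to_signal_ratio=1.5)
        assert len(dropped.peaks) == 0

    def test_flat_profile_empty(self):
        assert peakfinder_1d(np.ones((5, 50)), 1.0, 10.0).peaks == []

    def test_sum_projection_used(self):
        img = np.zeros((4, 60))
        img[:, 30] = 25.0  # column sum 100
        peaks = peakfinder_1d(img, min_prominence=50.0, max_width_cols=10.0)
        assert len(peaks.peaks) == 1 and peaks.peaks[0].height == 100.0

    def test_column_mask_covers_claimed_interval(self):
        prof = self.triangular(40, 100.0, 5)
        peaks = peakfinder_1d(prof[None, :], 50.0, 20.0)
        mask = peaks.to_column_mask()
        p = peaks.peaks[0]
        assert mask[0, p.col_start : p.col_stop + 1].all()
        assert mask.sum() == p.col_stop - p.col_start + 1
        full = peaks.to_mask((7, 100))
        assert full.shape == (7, 100)
        np.testing.assert_array_equal(full[0], full[6])


class TestSweep:
    def make_config(self):
        return AnalysisConfig(
            detection=[DetectionParams(sensitivity=0.2, neighborhood_size=15)],
            restriction=[RestrictionParams(y_edge_px=3, min_area_px2=5.0)],
            channel_names=["ch1"],
        )

    def test_grid_spans_optimum_interval(self):
        grid = sensitivity_grid(0.2, half_range=0.15, step=0.01)
        assert len(grid) == 31
        assert grid[0] == 0.05 and grid[-1] == 0.35 and 0.2 in grid

    def test_grid_clipped_to_unit_interval(self):
        grid = sensitivity_grid(0.05, half_range=0.15, step=0.05)
        assert grid[0] == 0.0 and grid[-1] == 0.2

    def test_identical_groups_not_separated(self):
        # same scenes in both genotypes: identical counts, p = 1
        crops = []
        for geno in ("a", "b"):
            for i in range(4):
                crop, _ = generate_scene(SceneSpec(n_puncta=8, seed=100 + i))
                crop.genotype = geno
                crop.crop_id = f"{geno}/{i}"
                crops.append(crop)
        res = sensitivity_sweep(
            CropDataset(crops=crops), self.make_config(), half_range=0.1, step=0.1
        )
        assert (res.pvalues["p_value"] >= 0.999).all()

    def test_distinct_counts_separated_across_grid(self):
        crops = []
        for geno, n in (("control", 12), ("severe", 3)):
            for i in range(6):
                crop, _ = generate_scene(SceneSpec(n_puncta=n, seed=200 + i))
                crop.genotype = geno
                crop.crop_id = f"{geno}/{i}"
                crops.append(crop)
        res = sensitivity_sweep(
            CropDataset(crops=crops), self.make_config(), half_range=0.15, step=0.15
        )
        assert res.grid == [0.05, 0.2, 0.35]
        assert (res.pvalues["p_value"] < 0.05).all()

    def test_small_genotype_excluded_with_warning(self):
        crops = []
        for geno, count in (("a", 3), ("b", 3), ("tiny", 1)):
            for i in range(count):
                crop, _ = generate_scene(SceneSpec(n_puncta=5, seed=300 + i))
                crop.genotype = geno
                crop.crop_id = f"{geno}/{i}"
                crops.append(crop)
        with pytest.warns(UserWarning, match="tiny"):
            res = sensitivity_sweep(
                CropDataset(crops=crops), self.make_config(), half_range=0.1, step=0.1
            )
        assert res.excluded_genotypes == ["tiny"]


class TestWelchDegenerate:
    def test_constant_equal_groups_p_one(self):
        import pandas as pd

        df = pd.DataFrame({"v": [5.0] * 6, "g": ["a"] * 3 + ["b"] * 3})
        assert welch_anova_p(df, "v", "g") == 1.0

    def test_constant_distinct_groups_p_zero(self):
        import pandas as pd

        df = pd.DataFrame({"v": [5.0] * 3 + [9.0] * 3, "g": ["a"] * 3 + ["b"] * 3})
        assert welch_anova_p(df, "v", "g") == 0.0


class TestMethodRanking:
    def test_local_means_beats_global_otsu_on_dim_scenes(self, det_params, restr_params):
        """On low-SNR scenes the adaptive threshold's balanced accuracy
        should be at least the global baseline's, and the 1D peakfinder
        should recover the fewest true signal columns."""
        from punctakit import analyze_channel, otsu_threshold
        from punctakit.detection import segment_rois
        from punctakit.roi_filtering import measure_rois, restrict_rois
        from punctakit.validation import confusion_rates

        ba_local, ba_otsu, tpr_local, tpr_peak = [], [], [], []
        det = DetectionParams(sensitivity=0.35, neighborhood_size=15)
        for seed in range(25):
            crop, truth = generate_scene(endogenous_like(n_puncta=10, seed=seed))
            ch = crop.channels[0]
            a = analyze_channel(ch, det, restr_params, 0.21)
            r_local = confusion_rates(a.labels > 0, truth > 0)
            lab_o = segment_rois(otsu_threshold(ch), ch)
            t_o = measure_rois(lab_o, ch, 0.21)
            lab_o, _ = restrict_rois(lab_o, t_o, restr_params)
            r_otsu = confusion_rates(lab_o > 0, truth > 0)
            peaks = peakfinder_1d(ch, min_prominence=80.0, max_width_cols=12.0)
            r_peak = confusion_rates(
                peaks.to_mask(ch.shape), truth > 0, mode="column1d"
            )
            ba_local.append(r_local.balanced_accuracy)
            ba_otsu.append(r_otsu.balanced_accuracy)
            tpr_local.append(
                confusion_rates(a.labels > 0, truth > 0, mode="column1d").tpr
            )
            tpr_peak.append(r_peak.tpr)
        assert np.mean(ba_local) >= np.mean(ba_otsu) - 0.02
        assert np.mean(tpr_peak) <= np.mean(tpr_local)
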