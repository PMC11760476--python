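"""Decision-tree contracts: Y gate, chrX LRR calibration, BAF windows."""

import numpy as np
import pytest

from ploidyscope import (
    EuploidLibrary,
    NoiseModel,
    SNPSample,
    ThresholdsConfig,
    TriploidyDecisionTree,
    XLrrBounds,
    baf_window_proportions,
    calibrate_baf_cutoffs,
    calibrate_x_lrr,
    chrx_mean_lrr,
    classify_3pn,
    classify_x_copies,
    simulate_library,
    simulate_sample,
    y_homozygosity,
)
from ploidyscope.core import CALL_AA, CALL_AB, CALL_NC
from ploidyscope.heterozygosity import DegenerateInputError
from ploidyscope.triploidy import CalibrationError

PAPER_BOUNDS = XLrrBounds(-1.0750221, -1.0396700)


def _constant_lrr_sample(manifest, x_lrr, sample_id="s"):
    n = len(manifest)
    calls = np.full(n, CALL_AA, dtype=np.int8)
    baf = np.zeros(n)
    lrr = np.zeros(n)
    lrr[manifest.is_x] = x_lrr
    return SNPSample(sample_id, manifest, calls, baf, lrr)


def _library_with_means(manifest, xy_means, xx_means):
    samples, labels = [], []
    for i, m in enumerate(xy_means):
        samples.append(_constant_lrr_sample(manifest, m, f"xy{i}"))
        labels.append("46XY")
    for i, m in enumerate(xx_means):
        samples.append(_constant_lrr_sample(manifest, m, f"xx{i}"))
        labels.append("46XX")
    return EuploidLibrary(samples, labels)


class TestYHomozygosity:
    def test_simulated_male_is_y_homozygous(self, manifest, noise, thresholds):
        s = simulate_sample(manifest, "46XY", noise, seed=1)
        flag, diag = y_homozygosity(s, thresholds)
        assert flag
        # oracle: direct count over chrY calls
        calls = s.calls[manifest.is_y]
        called = calls != CALL_NC
        assert diag["n_y_called"] == int(called.sum())
        assert diag["y_hom_fraction"] == pytest.approx(
            float((calls[called] != CALL_AB).mean()))

    def test_zero_called_y_markers_is_false(self, manifest, thresholds):
        s = simulate_sample(manifest, "46XX",
                            NoiseModel(y_stray_call_rate=0), seed=2)
        flag, diag = y_homozygosity(s, thresholds)
        assert not flag and diag["n_y_called"] == 0

    def test_simulated_female_with_stray_calls_is_false(self, manifest, noise,
                                                        thresholds):
        # default stray rate 0.01 on 120 chrY markers stays far below the
        # 10-marker floor
        for seed in range(10):
            s = simulate_sample(manifest, "46XX", noise, seed=seed)
            flag, _ = y_homozygosity(s, thresholds)
            assert not flag

    def test_manifest_without_y_rejected(self, thresholds):
        from ploidyscope import make_manifest

        m = make_manifest(10, 2, 1, seed=3)
        # drop the chrY rows to form an X-only manifest
        from ploidyscope import MarkerManifest

        m2 = MarkerManifest(m.table[m.table.chrom != "Y"])
        s = simulate_sample(m2, "46XY", NoiseModel(), seed=4)
        with pytest.raises(ValueError, match="chrY"):
            y_homozygosity(s, thresholds)


class TestChrxMeanLrr:
    def test_constant_value(self, small_manifest):
        s = _constant_lrr_sample(small_manifest, -1.0)
        assert chrx_mean_lrr(s) == pytest.approx(-1.0)

    def test_two_point_mean(self, tiny_manifest):
        n = len(tiny_manifest)
        # tiny manifest has a single X marker; use a two-X manifest instead
        import pandas as pd

        from ploidyscope import MarkerManifest

        t = tiny_manifest.table.copy()
        extra = pd.DataFrame({"marker_id": ["tX2"], "chrom": ["X"],
                              "pos": [200], "pop_b_freq": [0.5]})
        m = MarkerManifest(pd.concat([t, extra], ignore_index=True))
        s = _constant_lrr_sample(m, 0.0)
        s.lrr[m.is_x] = [-1.2, -0.8]
        assert chrx_mean_lrr(s) == pytest.approx(-1.0)

    def test_equals_brute_force_mean(self, small_manifest, noise):
        s = simulate_sample(small_manifest, "69XXY", noise, seed=5)
        vals = [v for v, isx in zip(s.lrr, small_manifest.is_x)
                if isx and np.isfinite(v)]
        assert chrx_mean_lrr(s) == pytest.approx(sum(vals) / len(vals))

    def test_all_missing_is_degenerate(self, small_manifest):
        s = _constant_lrr_sample(small_manifest, 0.0)
        s.lrr[small_manifest.is_x] = np.nan
        with pytest.raises(DegenerateInputError):
            chrx_mean_lrr(s)


class TestCalibration:
    def test_published_worked_example(self, small_manifest):
        lib = _library_with_means(
            small_manifest,
            xy_means=[-1.3, -1.2, -1.0750221],
            xx_means=[-1.0396700, -0.95],
        )
        bounds = calibrate_x_lrr(lib)
        assert bounds.one_copy_max == pytest.approx(-1.0750221, abs=1e-9)
        assert bounds.two_copy_min == pytest.approx(-1.0396700, abs=1e-9)

    def test_single_sample_extrema(self, small_manifest):
        lib = _library_with_means(small_manifest, [-2.0], [-1.0])
        assert calibrate_x_lrr(lib) == pytest.approx((-2.0, -1.0))

    def test_overlap_is_calibration_error(self, small_manifest):
        lib = _library_with_means(small_manifest, [-1.0], [-1.1])
        with pytest.raises(CalibrationError):
            calibrate_x_lrr(lib)

    def test_idempotent(self, manifest, noise):
        lib = simulate_library(manifest, 5, 5, noise, seed=6)
        assert calibrate_x_lrr(lib) == calibrate_x_lrr(lib)

    def test_simulated_library_calibrates_cleanly(self, manifest, noise):
        lib = simulate_library(manifest, 37, 32, noise, seed=7)
        bounds = calibrate_x_lrr(lib)
        assert bounds.one_copy_max < bounds.two_copy_min


class TestClassifyXCopies:
    @pytest.mark.parametrize(
        "mean_lrr,expected",
        [
            (-1.10, 1),
            (-1.0750221, 1),  # boundary <= is one copy, as published
            (-1.05, "indeterminate"),
            (-1.0396700, 2),  # boundary >= is two copies
            (-1.00, 2),
        ],
    )
    def test_published_bounds(self, mean_lrr, expected):
        assert classify_x_copies(mean_lrr, PAPER_BOUNDS) == expected


class TestBafWindows:
    def test_direct_count(self, tiny_manifest):
        # four autosomal BAF values 0.25/0.75/0.50/0.00 -> (0.25, 0.25)
        n = len(tiny_manifest)
        calls = np.full(n, CALL_AB, dtype=np.int8)
        baf = np.full(n, np.nan)
        aut_idx = np.where(tiny_manifest.is_autosomal)[0][:4]
        baf[aut_idx] = [0.25, 0.75, 0.50, 0.00]
        lrr = np.zeros(n)
        s = SNPSample("w", tiny_manifest, calls, baf, lrr)
        assert baf_window_proportions(s, ThresholdsConfig()) == (0.25, 0.25)

    def test_all_half_gives_zero(self, small_manifest, thresholds):
        n = len(small_manifest)
        s = SNPSample("h", small_manifest,
                      np.full(n, CALL_AB, dtype=np.int8),
                      np.full(n, 0.5), np.zeros(n))
        assert baf_window_proportions(s, thresholds) == (0.0, 0.0)

    def test_no_autosomal_baf_is_degenerate(self, small_manifest, thresholds):
        n = len(small_manifest)
        baf = np.full(n, np.nan)
        s = SNPSample("d", small_manifest,
                      np.full(n, CALL_NC, dtype=np.int8), baf, baf.copy())
        with pytest.raises(DegenerateInputError):
            baf_window_proportions(s, thresholds)

    def test_seeded_triploid_exceeds_cutoffs_and_matches_brute_force(
            self, manifest, thresholds):
        s = simulate_sample(manifest, "69XXX", NoiseModel(baf_sd=0.04), seed=8)
        lo, hi = baf_window_proportions(s, thresholds)
        # oracle: direct window count over the emitted autosomal BAF vector
        vals = [b for b, a in zip(s.baf, manifest.is_autosomal)
                if a and np.isfinite(b)]
        assert lo == pytest.approx(
            sum(0.2 <= b <= 0.3 for b in vals) / len(vals))
        assert hi == pytest.approx(
            sum(0.7 <= b <= 0.8 for b in vals) / len(vals))
        assert lo > thresholds.baf_cut_low and hi > thresholds.baf_cut_high

    def test_euploid_library_cutoff_calibration(self, manifest, noise,
                                                thresholds):
        lib = simulate_library(manifest, 3, 3, noise, seed=9)
        cut_low, cut_high = calibrate_baf_cutoffs(lib, thresholds)
        # euploid window mass is tiny relative to the published cut-offs
        assert 0 <= cut_low < thresholds.baf_cut_low
        assert 0 <= cut_high < thresholds.baf_cut_high


class TestClassify3pn:
    def test_truth_label_recovery_each_state(self, manifest, noise,
                                             thresholds):
        for state in ("46XX", "46XY", "69XXX", "69XXY"):
            s = simulate_sample(manifest, state, noise, seed=10)
            call = classify_3pn(s, thresholds)
            assert call.ploidy_class == state

    def test_y_negative_below_both_cutoffs_is_46xx(self, thresholds):
        # constructed Y-negative sample with window proportions exactly
        # (0.05, 0.04): strictly below (0.0589, 0.0431) -> 46XX
        from ploidyscope import make_manifest

        m = make_manifest(100, 2, 2, seed=30)
        n = len(m)
        calls = np.full(n, CALL_AB, dtype=np.int8)
        calls[m.is_y] = CALL_NC
        baf = np.full(n, 0.5)
        aut_idx = np.where(m.is_autosomal)[0]
        baf[aut_idx[:5]] = 0.25
        baf[aut_idx[5:9]] = 0.75
        baf[m.is_y] = np.nan
        s = SNPSample("ex", m, calls, baf, np.where(m.is_y, np.nan, 0.0))
        call = classify_3pn(s, thresholds)
        assert (call.baf_prop_low, call.baf_prop_high) == (0.05, 0.04)
        assert not call.y_homozygous
        assert call.ploidy_class == "46XX"

    def test_routing_and_window_rules(self, manifest, thresholds):
        # Y-negative, both proportions high -> 69XXX; mixed -> indeterminate
        s = simulate_sample(manifest, "69XXX", NoiseModel(), seed=11)
        call = classify_3pn(s, thresholds)
        assert not call.y_homozygous and call.ploidy_class == "69XXX"
        tweaked = ThresholdsConfig(baf_cut_low=0.99)  # force a mixed outcome
        call2 = classify_3pn(s, tweaked)
        assert call2.ploidy_class == "indeterminate"

    def test_routing_exclusivity(self, manifest, noise, thresholds):
        for state, seed in (("46XY", 12), ("69XXY", 13), ("46XX", 14),
                            ("69XXX", 15)):
            call = classify_3pn(simulate_sample(manifest, state, noise, seed),
                                thresholds)
            if call.ploidy_class in ("46XY", "69XXY"):
                assert call.y_homozygous
            if call.ploidy_class in ("46XX", "69XXX"):
                assert not call.y_homozygous

    def test_y_homozygous_but_x_indeterminate(self, manifest, thresholds):
        s = simulate_sample(manifest, "46XY", NoiseModel(), seed=16)
        # shift chrX LRR into the gap between the bounds
        s.lrr[manifest.is_x] = -1.05
        call = classify_3pn(s, thresholds)
        assert call.y_homozygous
        assert call.x_copies == "indeterminate"
        assert call.ploidy_class == "indeterminate"

    def test_calibration_requested_but_missing(self, manifest, noise):
        thr = ThresholdsConfig(x_lrr_one_copy_max="calibrate",
                               x_lrr_two_copy_min="calibrate")
        s = simulate_sample(manifest, "46XY", noise, seed=17)
        with pytest.raises(CalibrationError):
            classify_3pn(s, thr)


class TestDecisionTreeEstimator:
    def test_fit_without_library_uses_published_bounds(self, manifest, noise):
        clf = TriploidyDecisionTree().fit()
        assert clf.x_bounds_ == pytest.approx(tuple(PAPER_BOUNDS))
        preds = clf.predict([simulate_sample(manifest, "69XXY", noise, seed=18)])
        assert list(preds) == ["69XXY"]

    def test_fit_with_library_calibrates(self, manifest, noise):
        lib = simulate_library(manifest, 8, 8, noise, seed=19)
        clf = TriploidyDecisionTree().fit(lib.samples, lib.sex_labels)
        assert clf.x_bounds_ == calibrate_x_lrr(lib)

    def test_decision_table_columns(self, manifest, noise):
        clf = TriploidyDecisionTree().fit()
        table = clf.decision_table(
            [simulate_sample(manifest, "46XX", noise, seed=20)])
        assert {"sample_id", "y_homozygous", "chrx_mean_lrr", "baf_prop_low",
                "baf_prop_high", "ploidy_class"} <= set(table.columns)
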