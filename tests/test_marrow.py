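"""Vertebral statistics, the statistical threshold, and volumetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from marrowmap import (
    VertebralStatistics,
    VoxelGrid,
    compute_volumes,
    red_threshold,
    segment_marrow,
    suv_summary,
    vertebral_statistics,
)


def _grid(data, spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(data, dtype=float), spacing=spacing, role="PET")


class TestVertebralStatistics:
    def test_constant_field(self):
        suv = _grid(np.full((4, 4, 4), 2.0))
        roi = np.ones((4, 4, 4), dtype=bool)
        stats = vertebral_statistics(suv, roi, roi)
        assert stats.mean_suv == 2.0
        assert stats.sd_suv == 0.0
        assert stats.voxel_count == 64

    def test_textbook_sample_sd(self):
        data = np.zeros((1, 1, 3))
        data[0, 0] = [1.0, 2.0, 3.0]
        roi = np.ones((1, 1, 3), dtype=bool)
        stats = vertebral_statistics(_grid(data), roi, roi)
        assert stats.mean_suv == pytest.approx(2.0)
        assert stats.sd_suv == pytest.approx(1.0)  # n-1 denominator

    def test_only_intersection_counts(self):
        data = np.zeros((2, 2, 2))
        data[0, 0, 0] = data[0, 0, 1] = 5.0
        trab = np.zeros((2, 2, 2), dtype=bool)
        trab[0, 0, :] = True
        roi = np.ones((2, 2, 2), dtype=bool)
        stats = vertebral_statistics(_grid(data), trab, roi)
        assert stats.voxel_count == 2
        assert stats.mean_suv == 5.0

    def test_empty_intersection_rejected(self):
        suv = _grid(np.zeros((3, 3, 3)))
        trab = np.zeros((3, 3, 3), dtype=bool)
        trab[0, 0, 0] = True
        roi = np.zeros((3, 3, 3), dtype=bool)
        roi[2, 2, 2] = True
        with pytest.raises(ValueError, match="ROI"):
            vertebral_statistics(suv, trab, roi)

    def test_estimates_within_sampling_error(self):
        rng = np.random.default_rng(21)
        mu, sigma, n = 2.0, 0.2, 4000
        data = rng.normal(mu, sigma, (20, 20, 10))
        roi = np.zeros((20, 20, 10), dtype=bool)
        roi.ravel()[:n] = True
        stats = vertebral_statistics(_grid(data), roi, roi)
        se_mean = sigma / np.sqrt(n)
        se_sd = sigma / np.sqrt(2 * (n - 1))
        assert abs(stats.mean_suv - mu) < 3 * se_mean
        assert abs(stats.sd_suv - sigma) < 3 * se_sd


class TestRedThreshold:
    def test_zero_spread(self):
        assert red_threshold(VertebralStatistics(2.0, 0.0, 10, 2.5)) == 2.0

    def test_negative_threshold_warned_and_all_red_downstream(self):
        stats = VertebralStatistics(2.0, 1.0, 10, 2.5)
        with pytest.warns(UserWarning, match="negative"):
            thr = red_threshold(stats)
        assert thr == pytest.approx(-0.5)
        suv = _grid(np.abs(np.random.default_rng(0).normal(1, 1, (4, 4, 4))))
        trab = np.ones((4, 4, 4), dtype=bool)
        seg = segment_marrow(suv, trab, thr)
        assert not seg.yellow.any()  # non-negative SUV means everything is red

    def test_strictly_decreasing_in_k(self):
        thresholds = [
            red_threshold(VertebralStatistics(2.0, 0.4, 10, k)) for k in (0.5, 1.5, 2.5)
        ]
        assert thresholds[0] > thresholds[1] > thresholds[2]

    def test_invalid_statistics_rejected(self):
        with pytest.raises(ValueError):
            VertebralStatistics(2.0, -0.1, 10)
        with pytest.raises(ValueError):
            VertebralStatistics(2.0, 0.1, 1)
        with pytest.raises(ValueError):
            VertebralStatistics(2.0, 0.1, 10, multiplier=0.0)


class TestSegmentMarrow:
    def test_vacuous_cuts(self):
        rng = np.random.default_rng(1)
        suv = _grid(rng.uniform(1.0, 2.0, (5, 5, 5)))
        trab = rng.random((5, 5, 5)) > 0.4
        below = segment_marrow(suv, trab, 0.5)
        assert not below.yellow.any() and int(below.red.sum()) == int(trab.sum())
        above = segment_marrow(suv, trab, 5.0)
        assert not above.red.any()

    def test_tie_goes_to_yellow(self):
        # red marrow is strictly *above* the threshold
        suv = _grid(np.full((2, 2, 2), 1.5))
        trab = np.ones((2, 2, 2), dtype=bool)
        seg = segment_marrow(suv, trab, 1.5)
        assert not seg.red.any() and seg.yellow.all()

    def test_exclusion_mask_removed_from_analysis(self):
        suv = _grid(np.full((3, 3, 3), 2.0))
        trab = np.ones((3, 3, 3), dtype=bool)
        skull = np.zeros((3, 3, 3), dtype=bool)
        skull[0] = True
        seg = segment_marrow(suv, trab, 1.0, exclude=skull)
        assert int(seg.analyzed.sum()) == 18
        assert not seg.red[0].any()

    def test_grid_mismatch_rejected(self):
        suv = _grid(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="geometry"):
            segment_marrow(suv, np.ones((4, 4, 4), dtype=bool), 1.0)

    @pytest.mark.filterwarnings("ignore:red-marrow threshold")
    def test_multiplicative_suv_rescaling_invariance(self):
        # calibration errors that scale all SUVs also scale the statistical
        # threshold; the resulting segmentation is unchanged
        rng = np.random.default_rng(5)
        data = rng.uniform(0.1, 3.0, (6, 6, 6))
        trab = rng.random((6, 6, 6)) > 0.3
        roi = trab.copy()
        for c in (0.5, 3.0):
            base_thr = red_threshold(vertebral_statistics(_grid(data), trab, roi))
            scaled_thr = red_threshold(vertebral_statistics(_grid(c * data), trab, roi))
            assert scaled_thr == pytest.approx(c * base_thr)
            a = segment_marrow(_grid(data), trab, base_thr)
            b = segment_marrow(_grid(c * data), trab, scaled_thr)
            np.testing.assert_array_equal(a.red, b.red)


class TestVolumes:
    def test_thousand_voxels_at_2mm(self):
        red = np.zeros((10, 10, 20), dtype=bool)
        red.ravel()[:1000] = True
        trab = np.ones((10, 10, 20), dtype=bool)
        suv = _grid(np.where(red, 2.0, 0.1), spacing=(2.0, 2.0, 2.0))
        seg = segment_marrow(suv, trab, 1.0)
        report = compute_volumes(seg, trab, (2.0, 2.0, 2.0))
        assert report.rbv_ml == pytest.approx(8.0)

    @given(
        values=arrays(np.float64, (6, 6, 6), elements=st.floats(0, 5)),
        threshold=st.floats(-1, 6),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_conservation_exact_for_any_threshold(self, values, threshold):
        trab = values > 1.0  # arbitrary trabecular mask derived from the field
        if not trab.any():
            return
        suv = _grid(values)
        seg = segment_marrow(suv, trab, threshold)
        report = compute_volumes(seg, trab, (1.0, 1.0, 1.0))
        # conservation is exact on voxel counts; ml values only add rounding
        assert int(seg.red.sum()) + int(seg.yellow.sum()) == int(seg.analyzed.sum())
        assert report.rbv_ml + report.ybv_ml == pytest.approx(
            int(seg.analyzed.sum()) / 1000.0, rel=1e-12
        )
        assert report.ibv_ml >= max(report.rbv_ml, report.ybv_ml)


class TestSuvSummary:
    def test_uniform_field_unit_ratio(self):
        suv = _grid(np.full((4, 4, 4), 1.3))
        trab = np.ones((4, 4, 4), dtype=bool)
        spine = np.zeros((4, 4, 4), dtype=bool)
        spine[0] = True
        spinal, rob, ratio = suv_summary(suv, trab, spine)
        assert spinal == rob == 1.3
        assert ratio == 1.0

    def test_known_region_means(self):
        rng = np.random.default_rng(13)
        data = np.empty((10, 10, 10))
        spine = np.zeros((10, 10, 10), dtype=bool)
        spine[:5] = True
        data[spine] = rng.normal(2.0, 0.05, int(spine.sum()))
        data[~spine] = rng.normal(0.8, 0.05, int((~spine).sum()))
        trab = np.ones((10, 10, 10), dtype=bool)
        spinal, rob, ratio = suv_summary(_grid(data), trab, spine)
        assert ratio == pytest.approx(2.5, rel=0.05)

    def test_skull_exclusion_shifts_rob_mean_down(self):
        data = np.full((6, 6, 6), 1.0)
        skull = np.zeros((6, 6, 6), dtype=bool)
        skull[5] = True
        data[skull] = 10.0  # hot region: removing it must lower the ROB mean
        trab = np.ones((6, 6, 6), dtype=bool)
        spine = np.zeros((6, 6, 6), dtype=bool)
        spine[0] = True
        _, rob_with, _ = suv_summary(_grid(data), trab, spine)
        _, rob_without, _ = suv_summary(_grid(data), trab, spine, skull_roi=skull)
        assert rob_without < rob_with

    def test_empty_regions_rejected(self):
        suv = _grid(np.zeros((3, 3, 3)))
        trab = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError, match="spine"):
            suv_summary(suv, trab, np.zeros((3, 3, 3), dtype=bool))
        with pytest.raises(ValueError, match="rest-of-body"):
            suv_summary(suv, trab, trab)
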