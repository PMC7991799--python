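"""Gap segmentation: thresholding, cleft check, blob selection, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from woundkit.preprocess import enhance
from woundkit.segment import (
    ThresholdConfig,
    area_error_pct,
    binarize,
    central_cleft_present,
    compute_threshold,
    detect_gap,
    intersection_over_union,
    smooth_mask,
)


class TestComputeThreshold:
    def test_divides_histogram_mean_by_coefficient(self):
        img = np.full((10, 10), 1000.0)
        assert compute_threshold(img, 3.14) == pytest.approx(1000 / 3.14)

    def test_eight_bit_coefficient_arithmetic(self):
        img = np.full((10, 10), 0.44)
        assert compute_threshold(img, 2.2) == pytest.approx(0.2)

    def test_always_below_the_mean(self, rng):
        img = rng.random((32, 32))
        assert compute_threshold(img, 1.01) < img.mean()

    def test_rejects_coefficient_at_or_below_one(self):
        with pytest.raises(ValueError):
            compute_threshold(np.ones((4, 4)), 1.0)


class TestThresholdConfig:
    def test_default_coefficients_per_profile(self):
        assert ThresholdConfig(bit_depth_profile=16).coefficient == 3.14
        assert ThresholdConfig(bit_depth_profile=8).coefficient == 2.2
        assert ThresholdConfig(bit_depth_profile=16,
                               low_contrast_mode=True).coefficient == 2.2
        assert ThresholdConfig(bit_depth_profile=8,
                               low_contrast_mode=True).coefficient == 1.2

    def test_explicit_T_overrides(self):
        assert ThresholdConfig(T=2.5).coefficient == 2.5
        with pytest.raises(ValueError):
            ThresholdConfig(T=0.9)


class TestBinarize:
    def test_nothing_below_threshold(self):
        img = np.ones((8, 8))
        assert not binarize(img, 0.5).any()

    def test_threshold_above_max_selects_all(self):
        img = np.random.default_rng(3).random((8, 8))
        assert binarize(img, 2.0).all()

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_per_pixel_comparison(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((16, 16))
        thr = rng.random()
        got = binarize(img, thr)
        expected = np.array([[img[i, j] < thr for j in range(16)]
                             for i in range(16)])
        np.testing.assert_array_equal(got, expected)


class TestSmoothMask:
    def test_solid_rectangle_is_fixed_point(self):
        raw = np.zeros((40, 40), dtype=bool)
        raw[10:30, 8:32] = True
        out = smooth_mask(raw, radius=2)
        np.testing.assert_array_equal(out[12:28, 10:30], True)
        assert abs(int(out.sum()) - int(raw.sum())) <= 40

    def test_one_pixel_notch_is_sealed(self):
        raw = np.zeros((40, 40), dtype=bool)
        raw[10:30, 10:30] = True
        raw[10:20, 20] = False  # 1-px slit from the top edge
        out = smooth_mask(raw, radius=2)
        assert out[12:18, 20].all()

    def test_empty_stays_empty(self):
        out = smooth_mask(np.zeros((16, 16), dtype=bool), radius=2)
        assert not out.any()


class TestCentralCleftPresent:
    def test_centered_blob_detected(self):
        grid = np.zeros((60, 60), dtype=bool)
        grid[25:35, 25:35] = True
        assert central_cleft_present(grid, min_area_px=50)

    def test_corner_blobs_rejected(self):
        grid = np.zeros((60, 60), dtype=bool)
        grid[:8, :8] = True
        grid[-8:, -8:] = True
        assert not central_cleft_present(grid, min_area_px=10)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_component_scan(self, seed):
        rng = np.random.default_rng(seed)
        grid = np.zeros((45, 45), dtype=bool)
        for _ in range(rng.integers(1, 5)):
            r, c = rng.integers(0, 40, 2)
            h, w = rng.integers(2, 8, 2)
            grid[r:r + h, c:c + w] = True
        min_area = int(rng.integers(1, 40))

        labels, n = ndi.label(grid, structure=np.ones((3, 3), int))
        expected = False
        for lab in range(1, n + 1):
            comp = labels == lab
            if comp.sum() < min_area:
                continue
            rr, cc = np.nonzero(comp)
            cr, cc_ = rr.mean(), cc.mean()
            if 15 <= cr <= 30 and 15 <= cc_ <= 30:
                expected = True
        assert central_cleft_present(grid, min_area) == expected


class TestDetectGap:
    def test_recovers_synthetic_gap_within_five_percent(self, small_sequence):
        frame, gt = small_sequence.frames[0], small_sequence.gt_masks[0]
        mask = detect_gap(enhance(frame), min_area_px=2000)
        assert area_error_pct(mask, gt) < 5.0

    def test_confluent_field_yields_empty_mask(self, constant_frame):
        mask = detect_gap(enhance(constant_frame), min_area_px=100)
        assert mask.is_empty
        assert mask.area_px == 0
        assert not mask.mask.any()

    def test_corner_shadow_excluded_from_gap(self):
        # synthetic enhanced-like image: bright field, dark central band,
        # dark corner patch that must not be picked
        img = np.full((90, 120), 0.6)
        img[:, 50:70] = 0.02       # central gap band
        img[:20, :25] = 0.01       # corner shadow
        mask = detect_gap(img, min_area_px=500)
        assert not mask.is_empty
        assert mask.mask[45, 60]
        assert not mask.mask[5, 5]

    def test_single_connected_component(self, small_sequence):
        for frame in small_sequence.frames[::4]:
            mask = detect_gap(enhance(frame), min_area_px=2000)
            if not mask.is_empty:
                _, n = ndi.label(mask.mask, structure=np.ones((3, 3), int))
                assert n == 1

    def test_raising_T_never_grows_the_gap(self, small_sequence):
        img = enhance(small_sequence.frames[0])
        areas = []
        for T in (2.0, 3.14, 5.0):
            cfg = ThresholdConfig(T=T, max_retries=0)
            areas.append(detect_gap(img, cfg, min_area_px=2000).area_px)
        assert areas[0] >= areas[1] >= areas[2]

    def test_contour_is_closed_on_boundary(self, small_sequence):
        mask = detect_gap(enhance(small_sequence.frames[0]),
                          min_area_px=2000)
        contour = mask.contour
        assert len(contour) > 10
        np.testing.assert_allclose(contour[0], contour[-1])

    def test_retry_loop_reports_attempts(self):
        # an image whose mean/T threshold finds nothing: all pixels equal
        img = np.full((60, 60), 0.5)
        cfg = ThresholdConfig(T=3.14, max_retries=3)
        mask = detect_gap(img, cfg, min_area_px=10)
        assert mask.is_empty
        assert mask.retries_used == 3


class TestAreaErrorPct:
    def test_identical_masks_have_zero_error(self):
        ref = np.zeros((20, 20), dtype=bool)
        ref[5:15, 5:15] = True
        assert area_error_pct(ref.copy(), ref) == 0.0

    def test_paper_scale_arithmetic(self):
        ref = np.zeros((200, 200), dtype=bool)
        ref.ravel()[:10_000] = True
        mask = np.zeros((200, 200), dtype=bool)
        mask.ravel()[:10_256] = True
        assert area_error_pct(mask, ref) == pytest.approx(2.56)

    def test_half_area_subset_is_fifty_percent(self):
        ref = np.zeros((20, 20), dtype=bool)
        ref[:10, :10] = True
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10, :5] = True
        assert area_error_pct(mask, ref) == pytest.approx(50.0)

    def test_empty_reference_flags_infinity(self):
        empty = np.zeros((8, 8), dtype=bool)
        one = empty.copy()
        one[4, 4] = True
        assert area_error_pct(empty.copy(), empty) == 0.0
        assert np.isinf(area_error_pct(one, empty))


def test_iou_of_empty_masks_is_perfect():
    empty = np.zeros((8, 8), dtype=bool)
    assert intersection_over_union(empty.copy(), empty) == 1.0
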