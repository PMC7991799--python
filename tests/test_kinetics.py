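"""Closure kinetics: series assembly, wound length, window fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from woundkit.kinetics import (
    ClosureSeries,
    build_series,
    edge_velocity,
    estimate_wound_length,
    find_linear_window,
    fit_window,
    moving_average_trailing,
)
from woundkit.segment import WoundMask
from woundkit.synthgen import simulate_sequence

from conftest import small_config


def mask_from(grid: np.ndarray) -> WoundMask:
    grid = np.asarray(grid, dtype=bool)
    return WoundMask(mask=grid, area_px=int(grid.sum()),
                     contour=np.empty((0, 2)), centroid=None,
                     is_empty=not grid.any(), threshold_used=0.0)


def masks_with_areas(areas_px, shape=(40, 60)):
    """Masks whose pixel counts follow the given sequence (left-anchored
    vertical bands so area control is exact)."""
    out = []
    for a in areas_px:
        g = np.zeros(shape, dtype=bool)
        cols = int(round(a / shape[0]))
        g[:, :cols] = True
        out.append(mask_from(g))
    return out


def series_of(areas_um2, t_hours, L_um=100.0, N=6):
    areas = np.asarray(areas_um2, float)
    dt = np.abs(areas[0] - areas)
    return ClosureSeries("s", np.asarray(t_hours, float), areas,
                         float(areas[0]), dt,
                         moving_average_trailing(dt, N), L_um, N=N)


class TestMovingAverage:
    def test_linear_sequence_slope_preserved(self):
        vals = np.arange(20.0) * 3.0
        sm = moving_average_trailing(vals, 6)
        np.testing.assert_allclose(np.diff(sm[6:]), 3.0)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 9))
    def test_matches_brute_force_window_mean(self, seed, N):
        rng = np.random.default_rng(seed)
        vals = rng.random(int(rng.integers(N, 30)))
        got = moving_average_trailing(vals, N)
        expected = [vals[max(0, i - N + 1):i + 1].mean()
                    for i in range(len(vals))]
        np.testing.assert_allclose(got, expected)


class TestBuildSeries:
    def test_constant_areas_give_zero_displacement(self):
        masks = masks_with_areas([1200] * 8)
        s = build_series(masks, t_hours=np.arange(8) / 6,
                         pixel_size_um=2.0, wound_length_um=80.0)
        np.testing.assert_array_equal(s.DT_um2, 0.0)
        np.testing.assert_array_equal(s.smoothed_DT_um2, 0.0)

    def test_arithmetic_decrement_accumulates_displacement(self):
        # areas drop by 250 px = 1000 um^2 per frame at 2 um pixels
        masks = masks_with_areas(2000 - 250 * np.arange(8), shape=(50, 60))
        s = build_series(masks, t_hours=np.arange(8.0),
                         pixel_size_um=2.0, wound_length_um=100.0)
        np.testing.assert_allclose(s.DT_um2, 1000.0 * np.arange(8))
        np.testing.assert_allclose(np.diff(s.smoothed_DT_um2[6:]), 1000.0)

    def test_area_unit_conversion(self):
        masks = masks_with_areas([400], shape=(40, 60))
        s = build_series(masks, t_hours=[0.0], pixel_size_um=3.0,
                         wound_length_um=50.0, N=1)
        assert s.area_um2[0] == pytest.approx(masks[0].area_px * 9.0)

    def test_rejects_empty_and_bad_length(self):
        with pytest.raises(ValueError):
            build_series([], t_hours=[], pixel_size_um=1.0,
                         wound_length_um=10.0)
        with pytest.raises(ValueError):
            build_series(masks_with_areas([10] * 6),
                         t_hours=np.arange(6.0), pixel_size_um=1.0,
                         wound_length_um=-1.0)


class TestEstimateWoundLength:
    def test_full_height_band_returns_field_height(self):
        g = np.zeros((100, 160), dtype=bool)
        g[:, 60:100] = True
        # 100 rows at 10 um/px -> 1000 um tall field
        assert estimate_wound_length(g, 10.0) == pytest.approx(1000.0)

    def test_rotated_band_measures_along_width(self):
        g = np.zeros((160, 100), dtype=bool)
        g[60:100, :] = True
        assert estimate_wound_length(g, 10.0) == pytest.approx(1000.0)

    def test_tilted_scratch_matches_programmed_chord(self):
        seq = simulate_sequence(small_config(seed=5, scratch_angle_deg=8.0,
                                             duration_hours=0.5))
        L = estimate_wound_length(seq.gt_masks[0], 2.6)
        assert L == pytest.approx(seq.wound_length_um, rel=0.02)

    def test_wide_nearly_square_band_not_inflated(self):
        # a band wider than the field is tall: the degenerate-covariance
        # case where a naive major axis drifts to the diagonal
        g = np.zeros((96, 256), dtype=bool)
        g[:, 60:180] = True
        assert estimate_wound_length(g, 1.0) == pytest.approx(96.0, rel=0.01)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            estimate_wound_length(np.zeros((8, 8), dtype=bool), 1.0)


class TestEdgeVelocity:
    def test_zero_displacement_zero_velocity(self):
        assert edge_velocity(0.0, 1.0, 500.0) == 0.0

    def test_two_edges_share_the_area_rate(self):
        assert edge_velocity(2000.0, 1.0, 1000.0) == pytest.approx(1.0)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        dA, dt, L = rng.uniform(0.1, 1e5), rng.uniform(0.1, 24), \
            rng.uniform(10, 2000)
        assert edge_velocity(dA, dt, L) == pytest.approx(dA / dt / L / 2,
                                                         rel=1e-12)

    def test_rejects_nonpositive_denominators(self):
        with pytest.raises(ValueError):
            edge_velocity(1.0, 0.0, 10.0)
        with pytest.raises(ValueError):
            edge_velocity(1.0, 1.0, 0.0)


class TestFitWindow:
    def test_noiseless_line_recovered_exactly(self):
        t = np.arange(0, 12.001, 1 / 6)
        # d(t) = 10 t um  ->  DT = 2 L d(t)
        L = 500.0
        areas = 1e6 - 2 * L * 10.0 * t
        s = series_of(areas, t, L_um=L, N=1)
        est = fit_window(s, (5.0, 11.0))
        assert est.v_um_per_h == pytest.approx(10.0, abs=1e-9)
        assert est.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_zero_velocity(self):
        t = np.arange(0, 12.001, 0.5)
        s = series_of(np.full_like(t, 5e5), t)
        est = fit_window(s, (5.0, 11.0))
        assert est.v_um_per_h == 0.0

    def test_matches_closed_form_ols(self, rng):
        t = np.arange(0, 12.001, 1 / 6)
        L = 400.0
        d = 8.0 * t + rng.normal(0, 2.0, len(t))
        areas = 8e5 - 2 * L * d
        s = series_of(areas, t, L_um=L, N=1)
        est = fit_window(s, (5.0, 11.0))

        sel = (t >= 5.0) & (t <= 11.0)
        x, y = t[sel], s.DT_um2[sel] / (2 * L)
        n = len(x)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        resid = y - (y.mean() + slope * (x - x.mean()))
        sem = np.sqrt(resid @ resid / (n - 2) / sxx)
        r2 = 1 - (resid @ resid) / ((y - y.mean()) ** 2).sum()

        assert est.v_um_per_h == pytest.approx(slope, abs=1e-9)
        assert est.sem == pytest.approx(sem, abs=1e-9)
        assert est.r2 == pytest.approx(r2, abs=1e-9)

    def test_ci_contains_slope_and_sem_consistency(self, rng):
        """On replicated noisy positions the slope SEM stays below half
        the 95% CI width (the internal-consistency check)."""
        t = np.arange(0, 12.001, 1 / 6)
        for seed in range(5):
            r = np.random.default_rng(seed)
            d = 12.0 * t + r.normal(0, 3.0, len(t))
            s = series_of(7e5 - 2 * 300.0 * d, t, L_um=300.0)
            est = fit_window(s, (5.0, 11.0))
            lo, hi = est.ci95
            assert lo <= est.v_um_per_h <= hi
            assert est.sem < (hi - lo) / 2.0
            assert 0.0 <= est.r2 <= 1.0

    def test_too_few_points_raises(self):
        t = np.array([0.0, 5.5, 12.0])
        s = series_of([1e5, 9e4, 8e4], t, N=1)
        with pytest.raises(ValueError):
            fit_window(s, (5.0, 11.0))


class TestFindLinearWindow:
    def test_linear_series_gets_earliest_full_window(self):
        t = np.arange(0, 12.001, 1 / 6)
        s = series_of(1e6 - 2 * 500.0 * 10.0 * t, t, L_um=500.0, N=1)
        res = find_linear_window(s)
        assert res.meets_r2
        assert res.window == (0.0, 12.0)

    def test_noiseless_line_same_slope_in_every_window(self):
        t = np.arange(0, 12.001, 1 / 6)
        s = series_of(1e6 - 2 * 500.0 * 10.0 * t, t, L_um=500.0, N=1)
        slopes = [fit_window(s, (a, a + 6.0)).v_um_per_h
                  for a in np.arange(0, 6.001, 0.5)]
        np.testing.assert_allclose(slopes, 10.0, atol=1e-9)

    def test_pure_noise_flagged_sub_threshold(self, rng):
        t = np.arange(0, 12.001, 1 / 6)
        s = series_of(5e5 + rng.normal(0, 1e4, len(t)), t, N=1)
        res = find_linear_window(s)
        assert not res.meets_r2
        assert res.estimate.r2 < 0.985

    def test_short_series_raises(self):
        t = np.arange(0, 3.001, 0.5)
        s = series_of(np.linspace(1e5, 9e4, len(t)), t, N=1)
        with pytest.raises(ValueError):
            find_linear_window(s)


class TestScaleEquivariance:
    def test_doubling_pixel_size_doubles_area_and_velocity(self):
        masks = masks_with_areas(3000 - 200 * np.arange(40), shape=(50, 80))
        t = np.arange(40) * 0.25
        kw = dict(t_hours=t, wound_length_um=100.0)
        s1 = build_series(masks, pixel_size_um=1.0, **kw)
        s2 = build_series(masks, pixel_size_um=2.0,
                          t_hours=t, wound_length_um=200.0)
        np.testing.assert_allclose(s2.area_um2, 4.0 * s1.area_um2)
        v1 = fit_window(s1, (2.0, 8.0)).v_um_per_h
        v2 = fit_window(s2, (2.0, 8.0)).v_um_per_h
        assert v2 == pytest.approx(2.0 * v1, rel=1e-12)
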