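"""Reproducible validation studies on the synthetic benchmark.

Each study regenerates seeded synthetic data, runs the full pipeline on
it and summarizes how well the programmed ground truth is recovered:
segmentation area error and gap-detection rate, edge-velocity recovery,
linear-window discovery, and the statistical power to detect a
programmed slowdown.  The studies are what the test suite and the
reproduction script both call; all sizes are arguments so they can be
scaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinetics, pipeline, synthgen
from .compare import compare_conditions


@dataclass
class SegmentationReport:
    preset: str
    mean_area_error_pct: float
    detection_rate: float
    n_frames: int


def segmentation_study(presets: tuple[str, ...] = ("linear-easy",
                                                   "decelerating"),
                       n_seeds: int = 5,
                       n_frames: int = 50,
                       base_seed: int = 101) -> list[SegmentationReport]:
    """Segment ``n_seeds`` sequences of ``n_frames`` per preset and score
    them against ground truth."""
    reports = []
    for preset in presets:
        errors, detected, total = [], 0, 0
        for k in range(n_seeds):
            cfg = synthgen.preset_config(
                preset,
                seed=base_seed + 7919 * k,
                frame_interval_hours=12.0 / (n_frames - 1),
            )
            seq = synthgen.simulate_sequence(cfg)
            score = pipeline.score_sequence(seq)
            errors.extend(score.area_errors_pct.tolist())
            detected += int(score.detected.sum())
            total += score.n_frames
        reports.append(SegmentationReport(
            preset=preset,
            mean_area_error_pct=float(np.mean(errors)),
            detection_rate=detected / total,
            n_frames=total,
        ))
    return reports


def velocity_recovery_study(speeds: tuple[float, ...] = (5.0, 15.0, 25.0),
                            runs_per_speed: int = 7,
                            window: tuple[float, float] = (5.0, 11.0),
                            base_seed: int = 211) -> list[dict]:
    """Full-pipeline velocity recovery: simulate, segment, fit the window,
    compare the fitted slope with the programmed edge speed."""
    out = []
    for v in speeds:
        for k in range(runs_per_speed):
            cfg = synthgen.preset_config(
                "velocity", seed=base_seed + 104729 * k + int(v),
                edge_speed_um_per_h=v)
            seq = synthgen.simulate_sequence(cfg)
            masks = pipeline.segment_sequence(seq.frames)
            series = kinetics.build_series(masks, seq.frames)
            est = kinetics.fit_window(series, window)
            out.append({
                "v_programmed": v,
                "v_fitted": est.v_um_per_h,
                "rel_err_pct": 100.0 * (est.v_um_per_h / v - 1.0),
                "r2": est.r2,
            })
    return out


def window_discovery_study(seed: int = 307) -> dict:
    """Linear-window discovery on the decelerating (sigmoid) and linear
    presets, through the full pipeline."""
    out = {}
    for preset in ("decelerating", "linear-easy"):
        cfg = synthgen.preset_config(preset, seed=seed)
        seq = synthgen.simulate_sequence(cfg)
        masks = pipeline.segment_sequence(seq.frames)
        series = kinetics.build_series(masks, seq.frames)
        res = kinetics.find_linear_window(series)
        full = kinetics.fit_window(series, (0.0, 12.0))
        out[preset] = {
            "window": res.window,
            "r2": res.estimate.r2,
            "meets_r2": res.meets_r2,
            "v_um_per_h": res.estimate.v_um_per_h,
            "full_fit_r2": full.r2,
        }
    return out


def sensitivity_power_study(slowdown: float = 0.15,
                            n_positions: int = 12,
                            n_reps: int = 50,
                            v_control: float = 15.0,
                            position_cv: float = 0.10,
                            base_seed: int = 401) -> float:
    """Power to detect a programmed fractional slowdown.

    Each repetition simulates ``n_positions`` control and treated
    positions (area series with between-position velocity scatter of
    ``position_cv``), fits the 5-11 h window per position, and tests the
    two groups.  Returns the fraction of repetitions with p < 0.05.
    """
    significant = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(base_seed + 6151 * rep)
        groups = {}
        for label, v_mean in (("control", v_control),
                              ("treated", v_control * (1.0 - slowdown))):
            fitted = []
            for _ in range(n_positions):
                v_true = rng.normal(v_mean, position_cv * v_mean)
                t, area, L = synthgen.simulate_area_series(v_true, rng)
                masks_free = np.abs(area[0] - area)
                series = kinetics.ClosureSeries(
                    position_id=label, t_hours=t, area_um2=area,
                    T0_area_um2=float(area[0]), DT_um2=masks_free,
                    smoothed_DT_um2=kinetics.moving_average_trailing(
                        masks_free, 6),
                    wound_length_um=L)
                fitted.append(kinetics.fit_window(series).v_um_per_h)
            groups[label] = fitted
        eff = compare_conditions(groups["treated"], groups["control"])
        significant += int(eff.significant)
    return significant / n_reps
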