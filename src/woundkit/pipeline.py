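"""End-to-end orchestration: library -> masks -> series -> estimates.

Thin glue over the processing modules; the CLI, validation helpers and
acceptance tooling all drive the pipeline through these functions so
that every entry point shares one deterministic code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io_library, kinetics, segment
from .io_library import Frame, LibraryManifest
from .preprocess import FilterParams, enhance
from .segment import ThresholdConfig, WoundMask
from .synthgen import SyntheticSequence

#: IoU with the ground truth above which a detection counts as "correctly
#: located"; an empty mask on a truly closed wound also counts.
DETECTION_IOU = 0.5


def segment_frame(frame: Frame,
                  filter_params: FilterParams | None = None,
                  threshold_cfg: ThresholdConfig | None = None,
                  min_area_px: int | None = None,
                  smooth_radius: int = 2,
                  fill_holes: bool = True) -> WoundMask:
    """Enhance one frame and detect its wound gap."""
    params = filter_params or FilterParams()
    cfg = threshold_cfg or ThresholdConfig(bit_depth_profile=frame.bit_depth)
    if min_area_px is None:
        min_area_px = segment.default_min_area_px(params.tophat_radius)
        min_area_px = min(min_area_px, frame.pixels.size // 20)
    img = enhance(frame, params)
    return segment.detect_gap(img, cfg, min_area_px=min_area_px,
                              smooth_radius=smooth_radius,
                              fill_holes=fill_holes)


def segment_sequence(frames: Sequence[Frame], **kwargs) -> list[WoundMask]:
    """Segment every frame of one position, in order."""
    return [segment_frame(f, **kwargs) for f in frames]


def segment_library(root: str | Path,
                    bit_depth: int = 16,
                    pixel_size_um: float = 1.3,
                    interval_hours: float = 1.0 / 6.0,
                    mask_root: str | Path | None = None,
                    **kwargs) -> dict[str, list[WoundMask]]:
    """Segment every position of a library, mirroring masks to
    ``<root>_masks`` (or ``mask_root``).  Returns masks per position."""
    manifest = io_library.scan_library(root, interval=interval_hours)
    root = Path(root)
    mask_root = Path(mask_root) if mask_root else root.parent / (root.name + "_masks")
    results: dict[str, list[WoundMask]] = {}
    for pid in manifest.position_ids:
        masks = []
        for frame, src in zip(
            io_library.iter_frames(manifest, pid, bit_depth, pixel_size_um),
            manifest.positions[pid],
        ):
            mask = segment_frame(frame, **kwargs)
            io_library.write_mask(mask, mask_root / pid / (src.stem + ".png"))
            masks.append(mask)
        results[pid] = masks
    return results


def analyze_library(root: str | Path,
                    bit_depth: int = 16,
                    pixel_size_um: float = 1.3,
                    interval_hours: float = 1.0 / 6.0,
                    window: tuple[float, float] = kinetics.DEFAULT_WINDOW,
                    smooth_n: int = kinetics.DEFAULT_SMOOTH_N,
                    wound_length_um: float | None = None,
                    out_series_csv: str | Path | None = None,
                    out_estimates_csv: str | Path | None = None,
                    **segment_kwargs):
    """Full analysis of a library: segmentation, series, window fits.

    Returns (series list, estimate list); optionally writes both tables.
    """
    manifest = io_library.scan_library(root, interval=interval_hours)
    series_list: list[kinetics.ClosureSeries] = []
    estimates: list[kinetics.VelocityEstimate] = []
    for pid in manifest.position_ids:
        frames = list(io_library.iter_frames(manifest, pid, bit_depth,
                                             pixel_size_um))
        masks = segment_sequence(frames, **segment_kwargs)
        series = kinetics.build_series(masks, frames,
                                       wound_length_um=wound_length_um,
                                       N=smooth_n)
        series_list.append(series)
        estimates.append(kinetics.fit_window(series, window))
    if out_series_csv:
        io_library.write_results_table(series_list, out_series_csv)
    if out_estimates_csv:
        io_library.write_results_table(estimates, out_estimates_csv)
    return series_list, estimates


# --------------------------------------------------------------------------
# validation against ground truth
# --------------------------------------------------------------------------

@dataclass
class SequenceScore:
    """Per-sequence segmentation accuracy vs ground truth."""

    area_errors_pct: np.ndarray   # only frames with a non-empty reference
    detected: np.ndarray          # bool per frame (all frames)
    n_frames: int

    @property
    def mean_area_error_pct(self) -> float:
        return float(self.area_errors_pct.mean()) if self.area_errors_pct.size \
            else float("nan")

    @property
    def detection_rate(self) -> float:
        return float(self.detected.mean())


def score_sequence(seq: SyntheticSequence,
                   masks: Sequence[WoundMask] | None = None,
                   **segment_kwargs) -> SequenceScore:
    """Segment a synthetic sequence (or take precomputed masks) and score
    it against its ground truth.

    A frame counts as *detected* when the mask overlaps the true gap with
    IoU >= 0.5, or when both are empty (a correctly recognized closed
    wound).  Area errors are reported for frames whose true gap is
    non-empty.
    """
    if masks is None:
        masks = segment_sequence(seq.frames, **segment_kwargs)
    errors, detected = [], []
    for mask, gt in zip(masks, seq.gt_masks):
        gt_any = bool(gt.any())
        iou = segment.intersection_over_union(mask, gt)
        detected.append(iou >= DETECTION_IOU if gt_any or not mask.is_empty
                        else True)
        if gt_any:
            errors.append(segment.area_error_pct(mask, gt))
    return SequenceScore(
        area_errors_pct=np.asarray(errors, dtype=float),
        detected=np.asarray(detected, dtype=bool),
        n_frames=len(masks),
    )
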