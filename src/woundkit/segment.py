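"""Wound-gap segmentation of enhanced frames.

The enhanced image (cells bright, gap dark) is binarized at a threshold
obtained by dividing the image histogram mean by a tunable coefficient T
(> 1).  The scratch assay guarantees an empty cleft in the middle of the
field, so the candidate mask is validated by a central-cleft check; on
failure the threshold is recomputed (multiplied by a retry factor) and
the check repeated a bounded number of times.  The largest qualifying
central component becomes the gap, its holes (detached pioneer cells)
are filled, and a closed contour is traced.  A fully closed wound yields
an empty mask — a valid outcome, never an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.morphology import closing, dilation, disk, erosion

#: Default threshold coefficients, empirically determined per camera bit
#: depth; low-contrast cell lines (thin lamellae, e.g. 3T3 / primary
#: fibroblasts) need laxer values.
DEFAULT_T = {8: 2.2, 16: 3.14}
LOW_CONTRAST_T = {8: 1.2, 16: 2.2}


@dataclass(frozen=True)
class ThresholdConfig:
    """Threshold coefficient and retry schedule for gap detection."""

    T: float | None = None
    bit_depth_profile: int = 16
    low_contrast_mode: bool = False
    max_retries: int = 5
    retry_factor: float = 0.85

    def __post_init__(self) -> None:
        if self.bit_depth_profile not in (8, 16):
            raise ValueError("bit_depth_profile must be 8 or 16")
        if self.T is not None and self.T <= 1:
            raise ValueError("T coefficient must be > 1")
        if not (0 < self.retry_factor < 1):
            raise ValueError("retry_factor must lie in (0, 1)")

    @property
    def coefficient(self) -> float:
        if self.T is not None:
            return self.T
        table = LOW_CONTRAST_T if self.low_contrast_mode else DEFAULT_T
        return table[self.bit_depth_profile]


@dataclass
class WoundMask:
    """Binary gap mask for one frame plus detection diagnostics."""

    mask: np.ndarray
    area_px: int
    contour: np.ndarray  # (n, 2) closed boundary in (row, col); empty if no gap
    centroid: tuple[float, float] | None
    is_empty: bool
    threshold_used: float
    retries_used: int = 0
    hole_area_px: int = 0  # area added by filling pioneer-cell holes

    @classmethod
    def empty(cls, shape: tuple[int, int], threshold: float,
              retries: int) -> "WoundMask":
        return cls(
            mask=np.zeros(shape, dtype=bool),
            area_px=0,
            contour=np.empty((0, 2)),
            centroid=None,
            is_empty=True,
            threshold_used=threshold,
            retries_used=retries,
        )


def compute_threshold(img: np.ndarray, T: float) -> float:
    """Binarization threshold: the image histogram mean divided by T."""
    if T <= 1:
        raise ValueError("T coefficient must be > 1")
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("cannot threshold an empty image")
    return float(img.mean()) / T


def binarize(img: np.ndarray, thr: float) -> np.ndarray:
    """Candidate gap mask: pixels strictly below the threshold."""
    return np.asarray(img) < thr


def smooth_mask(raw: np.ndarray, radius: int = 2) -> np.ndarray:
    """Contour smoothing: closing, dilation, closing, erosion.

    Applied with a minimal-radius disk so thin isthmuses connecting the
    gap to background clefts are sealed without degrading the contour.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    se = disk(radius)
    out = closing(raw, se)
    out = dilation(out, se)
    out = closing(out, se)
    out = erosion(out, se)
    return out.astype(bool)


def _central_components(candidate: np.ndarray, min_area_px: int):
    """Labelled components whose centroid lies in the middle third of both
    axes and whose area meets the floor.  Returns (labels, [(label, area)])."""
    labels, n = ndi.label(candidate, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return labels, []
    rows, cols = candidate.shape
    r_lo, r_hi = rows / 3.0, 2.0 * rows / 3.0
    c_lo, c_hi = cols / 3.0, 2.0 * cols / 3.0
    areas = ndi.sum_labels(candidate, labels, index=np.arange(1, n + 1))
    centroids = ndi.center_of_mass(candidate, labels, index=np.arange(1, n + 1))
    hits = [
        (lab, int(area))
        for lab, (area, (cr, cc)) in enumerate(zip(areas, centroids), start=1)
        if area >= min_area_px and r_lo <= cr <= r_hi and c_lo <= cc <= c_hi
    ]
    return labels, hits


def central_cleft_present(candidate: np.ndarray, min_area_px: int) -> bool:
    """True iff a sufficiently large connected component sits in the
    central third of the field — the scratch assay's signature cleft."""
    _, hits = _central_components(candidate, min_area_px)
    return bool(hits)


def _trace_contour(mask: np.ndarray) -> np.ndarray:
    """Closed boundary of the gap; padding keeps the loop closed even
    when the gap touches the image border."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.empty((0, 2))
    contour = max(contours, key=len) - 1.0
    np.clip(contour[:, 0], 0, mask.shape[0] - 1, out=contour[:, 0])
    np.clip(contour[:, 1], 0, mask.shape[1] - 1, out=contour[:, 1])
    return contour


def detect_gap(
    img: np.ndarray,
    cfg: ThresholdConfig | None = None,
    min_area_px: int | None = None,
    smooth_radius: int = 2,
    fill_holes: bool = True,
) -> WoundMask:
    """Detect the wound gap in an enhanced image.

    Threshold = mean / T; candidates below threshold are smoothed and
    checked for a central cleft.  If none is found the threshold is
    multiplied by ``retry_factor`` and the detection repeated, up to
    ``max_retries`` times.  On success the largest qualifying central
    component is selected, holes from detached pioneer cells are filled
    (their area counts toward the gap), and its closed contour traced.
    Exhausted retries return an *empty* mask — a closed wound is a valid
    result, not an error.
    """
    cfg = cfg or ThresholdConfig()
    img = np.asarray(img, dtype=np.float64)
    if min_area_px is None:
        min_area_px = default_min_area_px()

    thr = compute_threshold(img, cfg.coefficient)
    for attempt in range(cfg.max_retries + 1):
        candidate = smooth_mask(binarize(img, thr), smooth_radius)
        labels, hits = _central_components(candidate, min_area_px)
        if hits:
            best_label, _ = max(hits, key=lambda h: h[1])
            gap = labels == best_label
            if fill_holes:
                filled = ndi.binary_fill_holes(gap)
                hole_area = int(filled.sum() - gap.sum())
                gap = filled
            else:
                hole_area = 0
            return WoundMask(
                mask=gap,
                area_px=int(gap.sum()),
                contour=_trace_contour(gap),
                centroid=tuple(ndi.center_of_mass(gap)),
                is_empty=False,
                threshold_used=thr,
                retries_used=attempt,
                hole_area_px=hole_area,
            )
        thr *= cfg.retry_factor

    return WoundMask.empty(img.shape, thr, cfg.max_retries)


def default_min_area_px(tophat_radius: int = 25, factor: float = 50.0) -> int:
    """Minimum plausible gap area: ~``factor`` cell cross-sections, with
    the top-hat radius standing in for the cell radius in pixels."""
    return int(factor * tophat_radius**2)


def area_error_pct(mask: WoundMask | np.ndarray,
                   reference: np.ndarray) -> float:
    """Relative area error (percent) of a detected mask vs a reference.

    Both empty -> 0; reference empty but mask not -> +inf (flag value).
    """
    m = mask if isinstance(mask, np.ndarray) else mask.mask
    m = np.asarray(m, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if m.shape != reference.shape:
        raise ValueError("mask and reference dimensions differ")
    area_ref = int(reference.sum())
    area_m = int(m.sum())
    if area_ref == 0:
        return 0.0 if area_m == 0 else float("inf")
    return 100.0 * abs(area_m - area_ref) / area_ref


def intersection_over_union(mask: WoundMask | np.ndarray,
                            reference: np.ndarray) -> float:
    """Jaccard overlap between a detected mask and a reference; two empty
    masks agree perfectly (1.0)."""
    m = mask if isinstance(mask, np.ndarray) else mask.mask
    m = np.asarray(m, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    union = int((m | reference).sum())
    if union == 0:
        return 1.0
    return int((m & reference).sum()) / union
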