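"""Label-free image enhancement.

Transmitted-light frames of a scratched monolayer are converted into a
fluorescence-like grayscale image — cells bright, cell-free gap dark —
through five deterministic stages:

(a) intensity powering (contrast stretch that darkens the background),
(b) flat-field correction by a difference of Gaussians (removes uneven
    illumination),
(c) a local-entropy filter (textured cell regions map high, the smooth
    gap maps low),
(d) white top-hat background subtraction (removes structures wider than
    the structuring element, i.e. anything larger than a cell), and
(e) a small uniform average filter (suppresses dust and debris specks).

All filters use reflect padding so the field border is not misread as a
dark gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters.rank import entropy as _rank_entropy
from skimage.morphology import disk, white_tophat

from .io_library import Frame

#: Gray-level bins used by the entropy stage.  32 bins keep the estimate
#: well conditioned in a radius-4 disk (49 pixels) while preserving the
#: texture/no-texture contrast.
ENTROPY_BINS = 32


@dataclass(frozen=True)
class FilterParams:
    """Tunable parameters of the enhancement chain.

    Defaults target mammalian monolayers imaged at 10x: the top-hat
    radius approximates one cell diameter in pixels, the entropy radius
    about half a cell-texture wavelength.
    """

    power_exponent: float = 2.0
    sigma1: float = 2.0
    sigma2: float = 1.0
    entropy_radius: int = 4
    tophat_radius: int = 25
    average_kernel: int = 3

    def __post_init__(self) -> None:
        if self.power_exponent <= 0:
            raise ValueError("power_exponent must be > 0")
        if self.sigma1 < self.sigma2:
            raise ValueError("sigma1 must be >= sigma2")
        if self.entropy_radius < 1 or self.tophat_radius < 1:
            raise ValueError("filter radii must be >= 1")
        if self.average_kernel < 1 or self.average_kernel % 2 == 0:
            raise ValueError("average_kernel must be odd and >= 1")


def normalize_and_power(frame: Frame, exponent: float = 2.0) -> np.ndarray:
    """Stage (a): normalize to [0, 1] by bit depth and raise to ``exponent``.

    The map is monotone, so pixel ordering is preserved; exponents > 1
    darken the dim background relative to bright cell halos.
    """
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    scale = float(2 ** frame.bit_depth - 1)
    img = frame.pixels.astype(np.float64) / scale
    return img ** exponent


def flat_field_correct(img: np.ndarray, sigma1: float = 2.0,
                       sigma2: float = 1.0) -> np.ndarray:
    """Stage (b): difference-of-Gaussians flat-field correction.

    ``gaussian(img, sigma2) - gaussian(img, sigma1)`` is a band-pass whose
    response to slowly varying illumination (length scale >> sigma1) is
    ~0; the signed result is shifted to mid-gray: ``0.5 + dog / 2`` maps
    the possible range [-1, 1] into [0, 1].  A constant image maps to a
    constant 0.5.
    """
    img = np.asarray(img, dtype=np.float64)
    g2 = ndi.gaussian_filter(img, sigma2, mode="reflect")
    g1 = ndi.gaussian_filter(img, sigma1, mode="reflect")
    return 0.5 + (g2 - g1) / 2.0


def entropy_enhance(img: np.ndarray, radius: int = 4,
                    n_bins: int = ENTROPY_BINS) -> np.ndarray:
    """Stage (c): local Shannon entropy in a disk neighborhood.

    The [0, 1] image is quantized to ``n_bins`` gray levels and the
    per-pixel entropy of the disk(radius) neighborhood is computed, then
    rescaled by the log2(n_bins) upper bound back into [0, 1].  Textured
    (cellular) regions map high; smooth (gap) regions map near zero.

    The quantizer is offset by half a bin so that a bin is *centred* on
    mid-gray (0.5): the flat-field stage maps featureless background
    there, and without the offset mid-gray would sit exactly on a bin
    boundary, letting sensor noise dither between two codes and fake one
    bit of entropy in perfectly smooth regions.
    """
    if radius < 1:
        raise ValueError("entropy radius must be >= 1")
    img = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    quantized = np.minimum((img * n_bins + 0.5).astype(np.uint8), n_bins - 1)
    ent = _rank_entropy(quantized, disk(radius))
    return np.clip(ent / np.log2(n_bins), 0.0, 1.0)


def tophat_subtract(img: np.ndarray, radius: int = 25) -> np.ndarray:
    """Stage (d): white top-hat — image minus its morphological opening.

    Removes bright structures wider than ~2x the disk radius (illumination
    remnants, large plateaus) while keeping cell-scale peaks.  Output >= 0.
    """
    img = np.asarray(img, dtype=np.float64)
    # sequence decomposition keeps the large-disk opening tractable
    footprint = disk(radius, decomposition="sequence")
    return white_tophat(img, footprint)


def smooth_average(img: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Stage (e): uniform mean filter over a kernel x kernel window."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be odd and >= 1")
    if kernel == 1:
        return np.asarray(img, dtype=np.float64).copy()
    return ndi.uniform_filter(np.asarray(img, dtype=np.float64),
                              size=kernel, mode="reflect")


def enhance(frame: Frame, params: FilterParams | None = None) -> np.ndarray:
    """Run the full (a)–(e) chain on one frame.

    Returns a float image in [0, 1] in which the monolayer is bright and
    the wound gap dark, ready for threshold-based gap detection.
    """
    p = params or FilterParams()
    img = normalize_and_power(frame, p.power_exponent)
    img = flat_field_correct(img, p.sigma1, p.sigma2)
    img = entropy_enhance(img, p.entropy_radius)
    img = tophat_subtract(img, p.tophat_radius)
    img = smooth_average(img, p.average_kernel)
    return np.clip(img, 0.0, 1.0)
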