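"""Reading and writing of time-lapse image libraries.

A scratch-assay experiment is stored as a *library*: one directory per
imaging position, each holding an ordered sequence of grayscale frames
(TIFF, PNG or JPEG) acquired at a fixed interval after wounding.  This
module scans such libraries into a manifest, decodes individual frames,
and persists the binary wound masks and tabular results produced by the
rest of the pipeline.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type hints only
    from .kinetics import ClosureSeries, VelocityEstimate
    from .segment import WoundMask

IMAGE_EXTENSIONS = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}

# Rec. 601 luminance weights, used when an RGB frame sneaks in.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class Frame:
    """One grayscale frame with its acquisition metadata.

    Attributes
    ----------
    pixels : ndarray
        2-D non-negative integer intensity grid.
    bit_depth : int
        8 or 16; ``pixels`` must stay below ``2**bit_depth``.
    pixel_size_um : float
        Physical size of one pixel in micrometres (> 0).
    t_hours : float
        Acquisition time relative to the scratch, in hours.
    position_id : str
        Imaging-position label (library sub-folder name).
    frame_index : int
        Zero-based index within the position's sequence.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size_um: float
    t_hours: float
    position_id: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if px.size and int(px.max()) >= 2 ** self.bit_depth:
            raise ValueError(
                f"intensity {int(px.max())} exceeds {self.bit_depth}-bit range"
            )
        if px.size and int(px.min()) < 0:
            raise ValueError("pixels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class LibraryManifest:
    """Index of a scanned library: positions and their ordered frame files."""

    root_path: Path
    positions: dict[str, list[Path]]
    frame_interval_hours: float = 1.0 / 6.0
    treatment_label: dict[str, str] = field(default_factory=dict)
    control_flag: dict[str, bool] = field(default_factory=dict)

    @property
    def position_ids(self) -> list[str]:
        return list(self.positions)

    def n_frames(self, position_id: str) -> int:
        return len(self.positions[position_id])


def _natural_key(path: Path) -> tuple:
    """Sort key using the last integer in the file stem (acquisition counter)."""
    matches = re.findall(r"\d+", path.stem)
    return (int(matches[-1]) if matches else -1, path.name)


def scan_library(
    root: str | Path,
    interval: float = 1.0 / 6.0,
    metadata: Mapping[str, Mapping] | None = None,
) -> LibraryManifest:
    """Scan a library directory into a :class:`LibraryManifest`.

    Parameters
    ----------
    root : path
        Directory containing one sub-folder per imaging position.
    interval : float
        Hours between consecutive frames (default 10 min).
    metadata : mapping, optional
        Per-position ``{"treatment": str, "control": bool}`` entries.  If
        omitted and ``root/metadata.csv`` exists (columns ``position_id,
        treatment, control``), it is used instead.

    Raises
    ------
    FileNotFoundError
        If ``root`` does not exist.
    ValueError
        If no positions are found, a non-image file pollutes a position,
        or frames within a position disagree in shape.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"library root {root} does not exist")

    positions: dict[str, list[Path]] = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        files = [p for p in sub.iterdir() if p.is_file()]
        bad = [p for p in files if p.suffix.lower() not in IMAGE_EXTENSIONS]
        if bad:
            raise ValueError(f"non-image file in position {sub.name}: {bad[0].name}")
        if len(files) < 2:
            continue
        positions[sub.name] = sorted(files, key=_natural_key)

    if not positions:
        raise ValueError(f"no positions found under {root}")

    manifest = LibraryManifest(root_path=root, positions=positions,
                               frame_interval_hours=float(interval))

    meta = metadata
    sidecar = root / "metadata.csv"
    if meta is None and sidecar.is_file():
        df = pd.read_csv(sidecar, dtype={"position_id": str})
        meta = {
            str(r.position_id): {"treatment": str(r.treatment),
                                 "control": bool(r.control)}
            for r in df.itertuples()
        }
    if meta:
        for pid, entry in meta.items():
            if pid in positions:
                manifest.treatment_label[pid] = str(entry.get("treatment", ""))
                manifest.control_flag[pid] = bool(entry.get("control", False))

    _check_consistent_shapes(manifest)
    return manifest


def _check_consistent_shapes(manifest: LibraryManifest) -> None:
    """Probe first/last frame of each position for matching dimensions."""
    for pid, files in manifest.positions.items():
        first = _decode_gray(files[0])
        last = _decode_gray(files[-1])
        if first.shape != last.shape:
            raise ValueError(
                f"inconsistent sequence in position {pid}: "
                f"{files[0].name} is {first.shape}, {files[-1].name} is {last.shape}"
            )


def _decode_gray(path: Path) -> np.ndarray:
    """Decode an image file to a 2-D array; RGB collapses to luminance."""
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tf:
                if len(tf.pages) > 1:
                    warnings.warn(
                        f"multi-page TIFF {path.name}: using first plane",
                        stacklevel=2,
                    )
                arr = tf.pages[0].asarray()
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the file name
        raise ValueError(f"cannot decode image file {path}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA  # drop alpha if present
        arr = np.rint(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-plane grayscale image")
    return arr


def read_frame(
    path: str | Path,
    bit_depth: int,
    pixel_size_um: float,
    t_hours: float,
    position_id: str = "",
    frame_index: int = 0,
) -> Frame:
    """Read one image file into a :class:`Frame`.

    RGB inputs are converted to luminance; multi-page TIFFs use the first
    plane (with a warning).  Intensities above the stated bit depth raise.
    """
    arr = _decode_gray(Path(path))
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    if arr.size and arr.max() >= 2 ** bit_depth:
        raise ValueError(
            f"{path}: intensity {int(arr.max())} exceeds {bit_depth}-bit range"
        )
    return Frame(
        pixels=arr.astype(dtype),
        bit_depth=bit_depth,
        pixel_size_um=pixel_size_um,
        t_hours=t_hours,
        position_id=position_id,
        frame_index=frame_index,
    )


def iter_frames(
    manifest: LibraryManifest,
    position_id: str,
    bit_depth: int,
    pixel_size_um: float,
) -> Iterable[Frame]:
    """Yield the frames of one position in acquisition order."""
    for i, path in enumerate(manifest.positions[position_id]):
        yield read_frame(
            path,
            bit_depth=bit_depth,
            pixel_size_um=pixel_size_um,
            t_hours=i * manifest.frame_interval_hours,
            position_id=position_id,
            frame_index=i,
        )


def write_mask(mask: "WoundMask | np.ndarray", path: str | Path) -> None:
    """Write a binary wound mask as an 8-bit 0/255 image.

    An empty mask (fully closed wound) writes an all-zero image — closure
    is a valid outcome and still produces a file.
    """
    grid = mask if isinstance(mask, np.ndarray) else mask.mask
    out = np.where(np.asarray(grid, dtype=bool), 255, 0).astype(np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask image back to a boolean grid (nonzero = gap)."""
    return _decode_gray(Path(path)) > 0


RESULTS_COLUMNS = [
    "position_id", "frame_index", "t_hours", "gap_area_px", "gap_area_um2",
    "displacement_um2", "smoothed_displacement_um2", "edge_displacement_um",
]

ESTIMATE_COLUMNS = [
    "position_id", "t_start_h", "t_end_h", "v_um_per_h", "r2", "sem",
    "ci95_lo", "ci95_hi", "n_points",
]


def write_results_table(
    items: "Sequence[ClosureSeries] | Sequence[VelocityEstimate]",
    path: str | Path,
) -> pd.DataFrame:
    """Write closure series (one row per frame) or velocity estimates (one
    row per position) to CSV.  Returns the DataFrame written."""
    if len(items) == 0:
        raise ValueError("refusing to write an empty results table")

    rows: list[dict] = []
    first = items[0]
    if hasattr(first, "area_um2"):  # ClosureSeries
        for s in items:
            area_px = np.asarray(s.area_um2) / s.pixel_size_um**2
            for i, t in enumerate(s.t_hours):
                rows.append({
                    "position_id": s.position_id,
                    "frame_index": i,
                    "t_hours": t,
                    "gap_area_px": area_px[i],
                    "gap_area_um2": s.area_um2[i],
                    "displacement_um2": s.DT_um2[i],
                    "smoothed_displacement_um2": s.smoothed_DT_um2[i],
                    "edge_displacement_um":
                        s.smoothed_DT_um2[i] / (2.0 * s.wound_length_um),
                })
        columns = RESULTS_COLUMNS
    else:  # VelocityEstimate
        for e in items:
            rows.append({
                "position_id": e.position_id,
                "t_start_h": e.window[0],
                "t_end_h": e.window[1],
                "v_um_per_h": e.v_um_per_h,
                "r2": e.r2,
                "sem": e.sem,
                "ci95_lo": e.ci95[0],
                "ci95_hi": e.ci95[1],
                "n_points": e.n_points,
            })
        columns = ESTIMATE_COLUMNS

    df = pd.DataFrame(rows, columns=columns)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # repr-precision floats so a re-parse reproduces values exactly
    df.to_csv(path, index=False, float_format="%.17g")
    return df
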