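"""Image and report I/O, pixel calibration, maximum projection.

The pipeline works on 2-D maximum-projection fluorescence images of the four
CEP dopaminergic neurons in the *C. elegans* head.  Every size-dependent
operation (structuring elements, minimum peak separation, crop margins) is
expressed in physical units (µm) and converted to pixels through the camera
calibration, so the same defaults work across microscopes.

Conventions: row index 0 is the image top, coordinates are ``(row, col)``,
0-based, and all ranges are half-open.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "PixelCalibration",
    "ProjectionImage",
    "max_project",
    "load_image",
    "to_pixels",
    "write_report",
    "read_report",
]


@dataclasses.dataclass(frozen=True)
class PixelCalibration:
    """Physical size of one camera pixel.

    Parameters
    ----------
    pixel_size : float
        Edge length of one pixel in µm/pixel. Must be positive and finite.
    magnification_note : str, optional
        Free-text provenance (objective, camera, binning).
    """

    pixel_size: float
    magnification_note: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive and finite, got {self.pixel_size!r}")


@dataclasses.dataclass
class ProjectionImage:
    """A calibrated 2-D intensity field (maximum projection).

    ``intensities`` is a float array in the original camera units, i.e. within
    ``[0, 2**bit_depth - 1]``. Raw values are preserved on load; no rescaling
    is applied.
    """

    intensities: np.ndarray
    calibration: PixelCalibration
    bit_depth: int = 16
    source_path: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={arr.ndim}")
        if arr.shape[0] < 64 or arr.shape[1] < 64:
            raise ValueError(f"image too small ({arr.shape}); need at least 64x64 pixels")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if arr.min() < 0 or arr.max() > 2**self.bit_depth - 1:
            raise ValueError("intensities outside [0, 2**bit_depth - 1]")
        self.intensities = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def pixel_size(self) -> float:
        return self.calibration.pixel_size

    def normalized(self) -> np.ndarray:
        """Intensities rescaled to [0, 1] by full bit-depth range."""
        return self.intensities / (2**self.bit_depth - 1)


def max_project(
    stack: np.ndarray,
    calibration: PixelCalibration,
    bit_depth: int = 16,
    source_path: str = "",
) -> ProjectionImage:
    """Collapse a z-stack to 2-D by the per-pixel maximum over planes."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.shape[0] < 1 or stack.size == 0:
        raise ValueError("empty stack")
    return ProjectionImage(
        intensities=stack.max(axis=0).astype(float),
        calibration=calibration,
        bit_depth=bit_depth,
        source_path=source_path,
    )


def _infer_bit_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype in (np.uint16, np.int32, np.uint32):
        return 16
    # float TIFFs: infer from range
    return 8 if arr.max() <= 255 else 16


def load_image(path: str | Path, calibration: PixelCalibration) -> ProjectionImage:
    """Read a grayscale TIFF/PNG; multi-page TIFFs are max-projected.

    RGB images are rejected: the pipeline assumes single-channel GFP
    fluorescence and silently collapsing channels would corrupt intensities.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"cannot read image: {path}: {exc}") from exc

    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError(
            f"{path} is RGB(A); convert to a single-channel grayscale image first"
        )
    bit_depth = _infer_bit_depth(arr)
    if arr.ndim == 3:  # multi-page TIFF -> z-stack
        return max_project(arr, calibration, bit_depth=bit_depth, source_path=str(path))
    return ProjectionImage(
        intensities=arr.astype(float),
        calibration=calibration,
        bit_depth=bit_depth,
        source_path=str(path),
    )


def to_pixels(length_um: float, calibration: PixelCalibration) -> int:
    """Convert a physical length to a pixel count.

    Half-up rounding, floored at 1 for any positive length so structuring
    elements never degenerate at coarse pixel sizes. Zero maps to zero.
    """
    if length_um < 0:
        raise ValueError(f"length must be non-negative, got {length_um}")
    if length_um == 0:
        return 0
    return max(1, int(np.floor(length_um / calibration.pixel_size + 0.5)))


# -- metric report files ------------------------------------------------------

#: Fixed column order of the per-dendrite CSV report.
REPORT_COLUMNS: tuple[str, ...] = (
    "image_id",
    "dendrite_index",
    "dendrite_length",
    "dendrite_remaining",
    "break_count",
    "total_break_length",
    "dendrite_mean_intensity",
    "feature_count",
    "feature_count_per_length",
    "weighted_feature_count",
    "mean_feature_area",
    "mean_feature_circularity",
    "mean_feature_extent",
    "mean_feature_eccentricity",
    "mean_feature_min_caliper",
    "mean_feature_max_caliper",
    "mean_feature_intensity",
    "mean_feature_norm_location",
    "feature_location_dispersion",
    "mean_feature_distance_from_cell_body",
    "degeneration_category",
)


def write_report(
    rows: Sequence[dict],
    path: str | Path,
    run_params: dict | None = None,
) -> pd.DataFrame:
    """Write per-dendrite metric rows as CSV plus a JSON run-parameter side-car.

    Values round-trip at full precision (written with ``repr`` fidelity).
    Returns the DataFrame actually written.
    """
    path = Path(path)
    df = pd.DataFrame(list(rows), columns=list(REPORT_COLUMNS))
    try:
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise IOError(f"cannot write report to {path}: {exc}") from exc
    if run_params is not None:
        sidecar = path.with_suffix(".params.json")
        sidecar.write_text(json.dumps(run_params, indent=2, sort_keys=True))
    return df


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a metric report CSV written by :func:`write_report`."""
    return pd.read_csv(path, float_precision="round_trip")
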