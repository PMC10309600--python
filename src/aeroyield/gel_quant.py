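"""Rectangle-mask densitometry of PCR bands on gel images.

Each band is quantified as the arithmetic mean pixel intensity inside a
rectangle mask; all rectangles in one comparison must share the same size so
that means are comparable. Coordinates are 0-based and half-open:
``(row_start, col_start, height, width)`` covers rows
``row_start .. row_start+height-1``. Two-group band intensities are compared
with a pooled two-sample t-test.

Image I/O is restricted to plain formats: CSV matrices and (8/16-bit) PGM.
No background subtraction is applied by default; an optional rolling-minimum
background estimate is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import AeroYieldError
from .yield_performance import TTestResult, compare_yields

__all__ = [
    "GelImage",
    "Rectangle",
    "BandMeasurement",
    "quantify_bands",
    "compare_band_groups",
    "rolling_min_background",
    "read_gel_image",
]


class RectangleBoundsError(AeroYieldError, ValueError):
    pass


class RectangleSizeError(AeroYieldError, ValueError):
    pass


@dataclass(frozen=True)
class Rectangle:
    """0-based, half-open rectangle mask."""

    row_start: int
    col_start: int
    height: int
    width: int


@dataclass(frozen=True)
class GelImage:
    """A gel photograph as a nonnegative intensity matrix (camera units)."""

    intensities: np.ndarray
    lane_annotations: Optional[Tuple[str, ...]] = None

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"gel image must be 2-D, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("gel image intensities must be >= 0")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class BandMeasurement:
    lane_label: str
    rectangle: Rectangle
    mean_intensity: float
    group: str


def _check_rectangle(rect: Rectangle, shape: Tuple[int, int], label: str) -> None:
    r0, c0, h, w = rect.row_start, rect.col_start, rect.height, rect.width
    if h < 1 or w < 1:
        raise RectangleBoundsError(f"rectangle {label!r} has empty extent {h}x{w}")
    if r0 < 0 or c0 < 0 or r0 + h > shape[0] or c0 + w > shape[1]:
        raise RectangleBoundsError(
            f"rectangle {label!r} ({r0},{c0},{h},{w}) exceeds image shape {shape}"
        )


def quantify_bands(
    image: GelImage,
    rectangles: Sequence[Rectangle],
    *,
    lane_labels: Optional[Sequence[str]] = None,
    groups: Optional[Sequence[str]] = None,
) -> List[BandMeasurement]:
    """Mean pixel intensity inside each equal-sized rectangle mask."""
    lane_labels = list(lane_labels or [f"lane{i + 1}" for i in range(len(rectangles))])
    groups = list(groups or [""] * len(rectangles))
    sizes = {(r.height, r.width) for r in rectangles}
    if len(sizes) > 1:
        raise RectangleSizeError(
            f"all rectangles must share one size; got sizes {sorted(sizes)}"
        )
    out = []
    for rect, label, group in zip(rectangles, lane_labels, groups):
        _check_rectangle(rect, image.shape, label)
        block = image.intensities[
            rect.row_start : rect.row_start + rect.height,
            rect.col_start : rect.col_start + rect.width,
        ]
        out.append(
            BandMeasurement(
                lane_label=label,
                rectangle=rect,
                mean_intensity=float(block.mean()),
                group=group,
            )
        )
    return out


def compare_band_groups(group_a, group_b) -> TTestResult:
    """Pooled Student t-test of mean band intensities between two samplers."""
    return compare_yields(group_a, group_b, variant="pooled")


def rolling_min_background(image: GelImage, window: int = 25) -> np.ndarray:
    """Column-wise rolling-minimum background estimate (optional, off by default)."""
    from scipy.ndimage import minimum_filter1d

    return minimum_filter1d(image.intensities, size=window, axis=0, mode="nearest")


def read_gel_image(path) -> GelImage:
    """Read a gel image from a CSV matrix or an (8/16-bit) PGM file."""
    path = str(path)
    if path.endswith(".csv"):
        return GelImage(np.loadtxt(path, delimiter=","))
    if path.endswith(".pgm"):
        import imageio.v3 as iio

        return GelImage(np.asarray(iio.imread(path), dtype=float))
    raise ValueError(f"unsupported gel image format: {path} (use .csv or .pgm)")
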