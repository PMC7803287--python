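"""Fixation records, binary saccadic maps, and smoothed density maps.

A saccadic map marks every saccade landing pixel of every pooled subject
with a 1; Gaussian smoothing of that binary map (all subjects pooled first,
then smoothed) yields the human density map used as the empirical attention
distribution.  Coordinates are 0-based, ``x`` = column, ``y`` = row, origin
at the top-left corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import DataValidationError, DimensionError

__all__ = [
    "FixationRecord",
    "SaccadicMap",
    "DensityMap",
    "default_sigma",
    "build_saccadic_map",
    "build_density_map",
]


@dataclass(frozen=True)
class FixationRecord:
    """A single saccade landing position on an image."""

    image_id: str
    subject_id: str
    x: float
    y: float
    order: int | None = None  # 1 = first saccade


@dataclass
class SaccadicMap:
    """Binary map of saccade landing pixels (values in {0, 1})."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise DimensionError("saccadic map must be 2-D")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise DataValidationError("saccadic map values must be 0 or 1")
        self.values = self.values.astype(np.uint8)

    @property
    def n_marked(self) -> int:
        return int(self.values.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class DensityMap:
    """Gaussian-smoothed saccadic map; max-normalized unless stated."""

    values: np.ndarray
    sigma_px: float
    normalized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("density map must be 2-D")
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise DataValidationError("density map must be finite and nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def default_sigma(shape: Sequence[int]) -> float:
    """Default smoothing scale: 2% of the image diagonal, in pixels."""
    h, w = shape[:2]
    return 0.02 * math.hypot(h, w)


def build_saccadic_map(
    records: Iterable[FixationRecord],
    shape: Sequence[int],
    max_order: int | None = None,
) -> SaccadicMap:
    """Mark every landing pixel; duplicates collapse to a single 1.

    ``max_order`` keeps only records whose saccade index is <= max_order
    (records with no index recorded always pass).  Out-of-bounds records
    raise, naming the offending record.
    """
    h, w = int(shape[0]), int(shape[1])
    records = list(records)
    if not records:
        raise DataValidationError("no fixation records supplied")
    grid = np.zeros((h, w), dtype=np.uint8)
    kept = 0
    for rec in records:
        if max_order is not None and rec.order is not None and rec.order > max_order:
            continue
        col = int(round(rec.x))
        row = int(round(rec.y))
        if not (0 <= col < w and 0 <= row < h):
            raise DataValidationError(
                f"fixation out of bounds for {h}x{w} image: image_id="
                f"{rec.image_id!r} subject_id={rec.subject_id!r} x={rec.x} y={rec.y}"
            )
        grid[row, col] = 1
        kept += 1
    if kept == 0:
        raise DataValidationError(
            "no fixation records remain after saccade-order filtering"
        )
    return SaccadicMap(grid)


def build_density_map(
    smap: SaccadicMap,
    sigma_px: float | None = None,
    normalize: bool = True,
) -> DensityMap:
    """Gaussian blur of the binary saccadic map.

    The blur uses a zero ("constant") boundary so mass only leaves through
    the image border; the discretized kernel is normalized, hence interior
    fixations conserve total mass.  With ``normalize=True`` (default) the
    result is scaled so its maximum is 1.
    """
    if sigma_px is None:
        sigma_px = default_sigma(smap.shape)
    if sigma_px <= 0:
        raise DataValidationError(f"sigma must be positive, got {sigma_px}")
    if smap.n_marked == 0:
        raise DataValidationError("cannot smooth an all-zero saccadic map")
    blurred = ndimage.gaussian_filter(
        smap.values.astype(float), sigma=sigma_px, mode="constant"
    )
    if normalize:
        blurred = blurred / blurred.max()
    return DensityMap(blurred, sigma_px=float(sigma_px), normalized=normalize)
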