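"""Segmentation, contour extraction and geometric leaflet features.

Length, width and area summarize a planar leaflet segmentation: length is
the maximal vertical spreading among image columns, width the maximal
horizontal spreading among image rows, area the foreground pixel count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import LEAFLET_RESOLUTION_MM, LeafletImage

#: Default normalized segmentation threshold (gray level 115 on 0..255).
SEGMENTATION_THRESHOLD = 0.45


def threshold_gray_level(t: float = SEGMENTATION_THRESHOLD) -> int:
    """Gray level (0..255) corresponding to a normalized threshold."""
    return int(round(t * 255))


@dataclass
class BinaryMask:
    """A binary leaflet segmentation with physical pixel size."""

    pixels: np.ndarray
    resolution: float = LEAFLET_RESOLUTION_MM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if not np.isin(px, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.pixels = px.astype(np.uint8)


@dataclass
class ContourSet:
    """Finite set of 2D boundary points in (row, col) pixel coordinates."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if len(pts) != len(np.unique(pts, axis=0)):
            raise ValueError("contour points must be unique")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ShapeFeatures:
    length_px: float
    width_px: float
    area_px: float
    resolution: float = LEAFLET_RESOLUTION_MM

    @property
    def length_mm(self) -> float:
        return self.length_px * self.resolution

    @property
    def width_mm(self) -> float:
        return self.width_px * self.resolution

    @property
    def area_mm2(self) -> float:
        return self.area_px * self.resolution ** 2


def _as_array(image: LeafletImage | np.ndarray) -> tuple[np.ndarray, float]:
    if isinstance(image, LeafletImage):
        return image.pixels, image.resolution
    return np.asarray(image), LEAFLET_RESOLUTION_MM


def segment(image: LeafletImage | np.ndarray, t: float = SEGMENTATION_THRESHOLD,
            largest_component: bool = False) -> BinaryMask:
    """Threshold an intensity image into a binary mask (foreground iff > t).

    The strict inequality keeps the exact background value 0 out of the
    foreground for any nonnegative threshold.  ``largest_component``
    optionally keeps only the biggest 4-connected foreground component.
    """
    arr, res = _as_array(image)
    mask = (arr > t).astype(np.uint8)
    if largest_component and mask.any():
        labels, n = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    return BinaryMask(mask, resolution=res)


def _spreading(mask: np.ndarray, axis: int, mode: str) -> float:
    """Max spreading of the foreground along ``axis`` over the other axis."""
    if not mask.any():
        warnings.warn("empty mask: spreading is 0", stacklevel=3)
        return 0.0
    if mode == "extent":
        idx = np.arange(mask.shape[axis])
        shape = [1, 1]
        shape[axis] = -1
        idx = idx.reshape(shape)
        has = mask.any(axis=axis)
        first = np.where(has, np.where(mask, idx, mask.shape[axis]).min(axis=axis), 0)
        last = np.where(has, np.where(mask, idx, -1).max(axis=axis), -1)
        return float((last - first + 1).max())
    if mode == "run":
        # longest consecutive run of foreground along axis
        m = np.moveaxis(mask, axis, 0).astype(np.int64)
        best = np.zeros(m.shape[1], dtype=np.int64)
        cur = np.zeros(m.shape[1], dtype=np.int64)
        for row in m:
            cur = (cur + row) * row
            best = np.maximum(best, cur)
        return float(best.max())
    raise ValueError(f"unknown spreading mode {mode!r}")


def leaflet_length(mask: BinaryMask, mode: str = "extent") -> float:
    """Maximal leaflet spreading among all image columns (along rows)."""
    return _spreading(mask.pixels, axis=0, mode=mode)


def leaflet_width(mask: BinaryMask, mode: str = "extent") -> float:
    """Maximal leaflet spreading among all image rows (along columns)."""
    return _spreading(mask.pixels, axis=1, mode=mode)


def leaflet_area(mask: BinaryMask) -> float:
    """Number of foreground pixels."""
    return float(mask.pixels.sum())


def extract_contour(mask: BinaryMask) -> ContourSet:
    """Foreground pixels with a background 4-neighbour (borders count as background)."""
    px = mask.pixels
    if not px.any():
        raise ValueError("cannot extract a contour from an empty mask")
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    eroded = ndimage.binary_erosion(px, structure=cross, border_value=0)
    boundary = px.astype(bool) & ~eroded
    return ContourSet(np.argwhere(boundary))


def shape_features(image: LeafletImage | np.ndarray, t: float = SEGMENTATION_THRESHOLD,
                   mode: str = "extent") -> ShapeFeatures:
    """Segment an intensity image and measure length, width and area."""
    _, res = _as_array(image)
    mask = segment(image, t=t)
    return ShapeFeatures(length_px=leaflet_length(mask, mode=mode),
                         width_px=leaflet_width(mask, mode=mode),
                         area_px=leaflet_area(mask),
                         resolution=res)
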