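"""Evaluation metrics for predicted leaflet shapes.

Intensity agreement is measured with RMSE, region overlap with the Jaccard
similarity of the thresholded segmentations, and contour accuracy with the
Hausdorff distance and the average symmetric contour distance

    ASCD(X, Y) = (ACD(X, Y) + ACD(Y, X)) / 2,
    ACD(X, Y)  = (1/|X|) * sum_{x in X} min_{y in Y} d(x, y),

where d is the Euclidean distance between contour points.  Distances are in
pixels with an optional mm conversion (0.34 mm/pixel by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .features import SEGMENTATION_THRESHOLD, BinaryMask, ContourSet, extract_contour, segment
from .preprocess import LEAFLET_RESOLUTION_MM, LeafletImage


@dataclass
class MetricReport:
    """Per-leaflet metric values; contour fields are NaN for a failure case
    (an empty predicted segmentation has no contour)."""

    rmse: float
    jaccard: float
    hausdorff_px: float
    ascd_px: float
    resolution: float = LEAFLET_RESOLUTION_MM
    failure: bool = False

    @property
    def hausdorff_mm(self) -> float:
        return to_mm(self.hausdorff_px, self.resolution) if not self.failure else float("nan")

    @property
    def ascd_mm(self) -> float:
        return to_mm(self.ascd_px, self.resolution) if not self.failure else float("nan")


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean square difference between two same-shaped intensity grids."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def jaccard(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Intersection over union of two binary masks; 1.0 if both are empty."""
    am = (a.pixels if isinstance(a, BinaryMask) else np.asarray(a)).astype(bool)
    bm = (b.pixels if isinstance(b, BinaryMask) else np.asarray(b)).astype(bool)
    if am.shape != bm.shape:
        raise ValueError(f"shape mismatch: {am.shape} vs {bm.shape}")
    union = np.logical_or(am, bm).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(am, bm).sum() / union)


def _points(x: ContourSet | np.ndarray) -> np.ndarray:
    pts = x.points if isinstance(x, ContourSet) else np.asarray(x, dtype=np.float64)
    pts = pts.reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("contour metrics require nonempty point sets")
    return pts


def acd(x: ContourSet | np.ndarray, y: ContourSet | np.ndarray) -> float:
    """Directed average contour distance from x to y."""
    xp, yp = _points(x), _points(y)
    d, _ = cKDTree(yp).query(xp)
    return float(np.mean(d))


def ascd(x: ContourSet | np.ndarray, y: ContourSet | np.ndarray) -> float:
    """Average symmetric contour distance (mean of the two directed ACDs)."""
    return 0.5 * (acd(x, y) + acd(y, x))


def hausdorff(x: ContourSet | np.ndarray, y: ContourSet | np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets."""
    xp, yp = _points(x), _points(y)
    dxy, _ = cKDTree(yp).query(xp)
    dyx, _ = cKDTree(xp).query(yp)
    return float(max(dxy.max(), dyx.max()))


def to_mm(value_px: float, resolution: float = LEAFLET_RESOLUTION_MM) -> float:
    """Convert a pixel distance to mm."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if value_px < 0:
        raise ValueError("pixel distances are nonnegative")
    return value_px * resolution


def compare_leaflets(predicted: LeafletImage | np.ndarray,
                     truth: LeafletImage | np.ndarray,
                     t: float = SEGMENTATION_THRESHOLD) -> MetricReport:
    """All four metrics between a predicted and a ground-truth leaflet image.

    Both images are segmented at ``t``; an empty predicted (or true)
    segmentation yields a failure report with NaN contour metrics rather
    than a number.
    """
    parr = predicted.pixels if isinstance(predicted, LeafletImage) else np.asarray(predicted)
    tarr = truth.pixels if isinstance(truth, LeafletImage) else np.asarray(truth)
    res = truth.resolution if isinstance(truth, LeafletImage) else LEAFLET_RESOLUTION_MM
    err = rmse(parr, tarr)
    pmask = segment(parr, t=t)
    tmask = segment(tarr, t=t)
    jac = jaccard(pmask, tmask)
    if not pmask.pixels.any() or not tmask.pixels.any():
        return MetricReport(rmse=err, jaccard=jac, hausdorff_px=float("nan"),
                            ascd_px=float("nan"), resolution=res, failure=True)
    pc, tc = extract_contour(pmask), extract_contour(tmask)
    return MetricReport(rmse=err, jaccard=jac,
                        hausdorff_px=hausdorff(pc, tc), ascd_px=ascd(pc, tc),
                        resolution=res)
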