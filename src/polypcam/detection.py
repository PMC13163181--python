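"""Mask-derived polyp detection.

In deployment the polyp region comes from a trained detector; the
simulator supplies exact silhouette masks, so this module converts a
binary mask into the image-space quantities the sizing chain consumes:
a bounding box, a centroid and a pixel extent ``Obj_Pixel``.

Conventions (used everywhere, including file output): pixel boxes are
0-based, half-open ``(x0, y0, x1, y1)``; pixel coordinates are (x, y)
with the origin at the top-left pixel centre.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure as skmeasure

__all__ = ["ExtentMethod", "DepthStatistic", "Detection", "detect_from_mask", "pixel_extent", "region_depth"]


class ExtentMethod(str, enum.Enum):
    BBOX_LONG_SIDE = "bbox_long_side"
    BBOX_DIAGONAL = "bbox_diagonal"
    MAX_FERET = "max_feret"


class DepthStatistic(str, enum.Enum):
    MEDIAN = "median"
    MEAN = "mean"
    MIN = "min"
    CENTER_PIXEL = "center_pixel"


@dataclass
class Detection:
    """Image-space polyp region.

    ``pixel_extent`` is the scalar ``Obj_Pixel`` under ``extent_method``
    (default max-Feret diameter, matching the maximum-diameter
    convention used to ground-truth polyp size).
    """

    box: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    centroid: tuple[float, float]  # (x, y)
    pixel_extent: float
    extent_method: ExtentMethod
    mask: Optional[np.ndarray] = field(default=None, repr=False)
    extent_endpoints_px: Optional[np.ndarray] = None  # (2, 2) array of (x, y)
    hull_px: Optional[np.ndarray] = None  # (n, 2) convex-hull pixel coords (x, y)
    touches_border: bool = False

    @property
    def area_px(self) -> int:
        return int(self.mask.sum()) if self.mask is not None else 0


_CORNERS = np.array([[-0.5, -0.5], [0.5, -0.5], [-0.5, 0.5], [0.5, 0.5]])


def _feret(coords_xy: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Max pairwise distance over pixel *corners*, via the convex hull.

    Pixel corners (not centres) measure the area the region covers:
    for a single-row region of n pixels the extent is then >= n, which
    keeps bbox_long_side <= max_feret <= bbox_diagonal and halves the
    systematic underestimate of the underlying silhouette extent.
    Returns (extent, the two endpoints, the hull vertices).
    """
    pts = coords_xy.astype(float)
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear masks
            pass
    pts = (pts[:, None, :] + _CORNERS[None, :, :]).reshape(-1, 2)
    if len(pts) > 8:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff**2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    return float(np.sqrt(d2[i, j])), np.array([pts[i], pts[j]]), pts


def detect_from_mask(
    mask: np.ndarray,
    extent_method: ExtentMethod | str = ExtentMethod.MAX_FERET,
) -> Detection:
    """Build a :class:`Detection` from a binary mask.

    If the mask has several connected components the largest one is
    used.  Raises ``ValueError`` on an empty mask.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot detect a polyp in an empty mask")
    extent_method = ExtentMethod(extent_method)

    labels = skmeasure.label(mask, connectivity=2)
    if labels.max() > 1:
        sizes = np.bincount(labels.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        mask = labels == keep

    ys, xs = np.nonzero(mask)
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    centroid = (float(xs.mean()), float(ys.mean()))
    touches = x0 == 0 or y0 == 0 or x1 == mask.shape[1] or y1 == mask.shape[0]

    coords_xy = np.column_stack([xs, ys])
    feret, endpoints, hull = _feret(coords_xy)

    det = Detection(
        box=(x0, y0, x1, y1),
        centroid=centroid,
        pixel_extent=feret,
        extent_method=ExtentMethod.MAX_FERET,
        mask=mask,
        extent_endpoints_px=endpoints,
        hull_px=hull,
        touches_border=touches,
    )
    if extent_method is not ExtentMethod.MAX_FERET:
        det.pixel_extent = pixel_extent(det, extent_method)
        det.extent_method = extent_method
        det.extent_endpoints_px = None
    return det


def pixel_extent(detection: Detection, method: ExtentMethod | str) -> float:
    """Scalar extent of a detection under the chosen convention."""
    method = ExtentMethod(method)
    x0, y0, x1, y1 = detection.box
    w, h = x1 - x0, y1 - y0
    if method is ExtentMethod.BBOX_LONG_SIDE:
        return float(max(w, h))
    if method is ExtentMethod.BBOX_DIAGONAL:
        return float(np.hypot(w, h))
    if detection.mask is None:
        raise ValueError("max_feret extent requires the region mask")
    ys, xs = np.nonzero(detection.mask)
    feret, _, _ = _feret(np.column_stack([xs, ys]))
    return feret


def region_depth(
    depth_map,
    detection: Detection,
    statistic: DepthStatistic | str = DepthStatistic.MEDIAN,
) -> float:
    """``Obj_Distance``: a depth statistic over the detected region (mm)."""
    statistic = DepthStatistic(statistic)
    if detection.mask is None:
        raise ValueError("region_depth requires the detection mask")
    region = detection.mask & depth_map.valid
    n_bad = int((detection.mask & ~depth_map.valid).sum())
    if not region.any():
        raise ValueError(f"no valid depth pixels inside the detection ({n_bad} invalid)")
    vals = depth_map.values_mm[region]
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"{int(np.sum(~np.isfinite(vals)))} non-finite depth pixels inside the detection")
    if statistic is DepthStatistic.MEDIAN:
        return float(np.median(vals))
    if statistic is DepthStatistic.MEAN:
        return float(vals.mean())
    if statistic is DepthStatistic.MIN:
        return float(vals.min())
    # centre pixel: nearest valid pixel to the centroid
    cx, cy = detection.centroid
    ys, xs = np.nonzero(region)
    k = int(np.argmin((xs - cx) ** 2 + (ys - cy) ** 2))
    return float(depth_map.values_mm[ys[k], xs[k]])
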