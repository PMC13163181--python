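"""Camera models and the triangle-similarity polyp sizing chain.

The measurement principle is the pinhole proportionality

    Object_Size = Obj_Distance * Obj_Pixel / F_Pixel

refined by two corrections:

* **fish-eye correction** — wide-FOV endoscope lenses (here a 170°
  fish-eye) compress peripheral image content relative to a pinhole
  camera, so the raw pixel extent ``Obj_Pixel`` is mapped to a
  pinhole-equivalent extent ``Obj_Pixel_New`` before sizing;
* **polyp-thickness correction** — a monocular depth map reads the
  distance to the polyp's *near surface*, while triangle similarity
  wants the distance to the polyp body, so the polyp radius is added
  back:  ``Object_Size_Final = (Obj_Distance + Obj_Radius) *
  Obj_Pixel_New / F_Pixel``.

Angles are degrees at every public interface and radians internally.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Projection",
    "FisheyeMode",
    "CameraModel",
    "SizeEstimate",
    "initial_size",
    "fisheye_correct",
    "thickness_corrected_depth",
    "thickness_error_pct",
    "measure_polyp",
    "undistort_points",
]


class Projection(str, enum.Enum):
    """Lens projection model: ideal pinhole (r = f·tanθ) or the
    equidistant fish-eye model (r = f·θ)."""

    PINHOLE = "pinhole"
    EQUIDISTANT = "equidistant"


class FisheyeMode(str, enum.Enum):
    """How `fisheye_correct` maps a raw extent to a pinhole-equivalent one.

    AS_PRINTED     — dimensionless reading of the published formula:
                     Obj_Pixel_New = f · arctan(p/f) · (FOV_fisheye/FOV_normal).
    ANGULAR        — exact equidistant→pinhole conversion θ = r/f, r' = f·tanθ,
                     applied to the outline points when available.
    ANGULAR_EXTENT — f · (maximum pairwise angular distance between the
                     outline points' view rays): the angular Feret
                     diameter, rescaled to on-axis pixels.  Rotation-
                     invariant, hence position-correct for *sizing* at
                     any eccentricity (a pinhole-equivalent pixel extent
                     is not: triangle similarity is a near-axis
                     relation).  The equidistant-camera default.
    NONE           — identity (for images already in pinhole projection).
    """

    AS_PRINTED = "as_printed"
    ANGULAR = "angular"
    ANGULAR_EXTENT = "angular_extent"
    NONE = "none"


@dataclass(frozen=True)
class CameraModel:
    """Intrinsic camera description.

    Parameters
    ----------
    focal_length_px:
        Focal length ``F_Pixel`` in pixels.
    fov_fisheye_deg:
        Full field of view of the fish-eye lens (default 170°,
        a standard wide-angle colonoscope).
    fov_normal_deg:
        Full field of view of the reference "normal" camera used by the
        fish-eye correction (default 140°, a typical non-fish-eye
        endoscope spec).
    projection:
        Projection model the camera images under.
    image_width_px, image_height_px:
        Sensor size in pixels.
    principal_point:
        (cx, cy) in pixels; defaults to the image centre.
    """

    focal_length_px: float
    fov_fisheye_deg: float = 170.0
    fov_normal_deg: float = 140.0
    projection: Projection = Projection.EQUIDISTANT
    image_width_px: int = 256
    image_height_px: int = 256
    principal_point: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not self.focal_length_px > 0:
            raise ValueError(f"focal_length_px must be > 0, got {self.focal_length_px}")
        if not (0 < self.fov_normal_deg <= self.fov_fisheye_deg < 360):
            raise ValueError(
                "require 0 < fov_normal_deg <= fov_fisheye_deg < 360, got "
                f"normal={self.fov_normal_deg}, fisheye={self.fov_fisheye_deg}"
            )
        if self.image_width_px < 16 or self.image_height_px < 16:
            raise ValueError("image dimensions must be >= 16 px")
        if self.principal_point is None:
            object.__setattr__(
                self,
                "principal_point",
                ((self.image_width_px - 1) / 2.0, (self.image_height_px - 1) / 2.0),
            )
        if isinstance(self.projection, str):
            object.__setattr__(self, "projection", Projection(self.projection))

    @property
    def fov_ratio(self) -> float:
        """FOV_fisheye / FOV_normal, the correction gain of the published formula."""
        return self.fov_fisheye_deg / self.fov_normal_deg

    @property
    def half_fov_rad(self) -> float:
        return math.radians(self.fov_fisheye_deg) / 2.0

    @classmethod
    def for_fov(
        cls,
        fov_deg: float,
        projection: Projection | str = Projection.EQUIDISTANT,
        width: int = 256,
        height: int = 256,
        **kwargs,
    ) -> "CameraModel":
        """Build a camera whose *stated* FOV spans the image diagonal.

        Endoscope field-of-view specifications (e.g. 170°) quote the
        diagonal FOV, so f = (diag/2)/θ_half for an equidistant lens and
        (diag/2)/tan(θ_half) for a pinhole one.
        """
        projection = Projection(projection)
        half = math.radians(fov_deg) / 2.0
        half_diag = math.hypot(width, height) / 2.0
        if projection is Projection.EQUIDISTANT:
            f = half_diag / half
        else:
            if half >= math.pi / 2:
                raise ValueError("pinhole projection cannot span >= 180 deg")
            f = half_diag / math.tan(half)
        if projection is Projection.EQUIDISTANT:
            kwargs.setdefault("fov_fisheye_deg", fov_deg)
        kwargs.setdefault("fov_fisheye_deg", 170.0)
        kwargs.setdefault("fov_normal_deg", min(140.0, kwargs["fov_fisheye_deg"]))
        return cls(
            focal_length_px=f,
            projection=projection,
            image_width_px=width,
            image_height_px=height,
            **kwargs,
        )


@dataclass
class SizeEstimate:
    """Every intermediate of the sizing chain for one measurement."""

    obj_pixel: float
    obj_distance_mm: float
    obj_pixel_corrected: float
    size_initial_mm: float
    obj_radius_mm: float
    size_final_mm: float
    iterations: int = 1
    truncated: bool = False  # detection touched the image border
    fisheye_fallback: bool = False  # angular correction impossible (> 90° off-axis)

    def to_dict(self) -> dict:
        return asdict(self)


def _require_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


def initial_size(obj_pixel: float, obj_distance_mm: float, camera: CameraModel) -> float:
    """Triangle-similarity size: ``Obj_Distance * Obj_Pixel / F_Pixel`` (mm)."""
    _require_positive("obj_pixel", obj_pixel)
    _require_positive("obj_distance_mm", obj_distance_mm)
    return obj_distance_mm * obj_pixel / camera.focal_length_px


def pixel_to_direction(points: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Camera-frame unit view rays through pixel coordinates (n, 2)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cx, cy = camera.principal_point
    u = pts[:, 0] - cx
    v = pts[:, 1] - cy
    f = camera.focal_length_px
    if camera.projection is Projection.PINHOLE:
        d = np.stack([u / f, v / f, np.ones_like(u)], axis=-1)
    else:
        r = np.hypot(u, v)
        theta = r / f
        with np.errstate(invalid="ignore"):
            s = np.where(r > 0, np.sin(theta) / np.where(r > 0, r, 1.0), 0.0)
        d = np.stack([u * s, v * s, np.cos(theta)], axis=-1)
    return d / np.linalg.norm(d, axis=-1, keepdims=True)


def angular_extent_px(points: np.ndarray, camera: CameraModel) -> float:
    """f times the max pairwise angular distance between outline rays.

    For an on-axis object this equals its raw equidistant pixel extent;
    off-axis it removes the tangential stretch of the equidistant
    projection, so ``distance × extent / f`` remains a valid size
    estimate anywhere in the field of view.
    """
    d = pixel_to_direction(points, camera)
    dots = np.clip(d @ d.T, -1.0, 1.0)
    return float(camera.focal_length_px * np.arccos(dots).max())


def undistort_points(points: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Map equidistant-projected pixel coordinates to pinhole-equivalent ones.

    A point at radius r from the principal point images the view angle
    θ = r/f under the equidistant model; the same ray lands at
    r' = f·tanθ under a pinhole with the same focal length.  Azimuth is
    preserved.  Points at or beyond θ = 90° have no pinhole image and
    raise.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cx, cy = camera.principal_point
    d = pts - np.array([cx, cy])
    r = np.hypot(d[:, 0], d[:, 1])
    theta = r / camera.focal_length_px
    if np.any(theta >= math.pi / 2 - 1e-9):
        raise ValueError("point at >= 90 deg off-axis has no pinhole equivalent")
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r > 0, camera.focal_length_px * np.tan(theta) / np.where(r > 0, r, 1.0), 1.0)
    out = np.array([cx, cy]) + d * scale[:, None]
    return out if np.asarray(points).ndim == 2 else out[0]


def fisheye_correct(
    obj_pixel: float,
    obj_distance_mm: Optional[float],
    camera: CameraModel,
    mode: FisheyeMode | str = FisheyeMode.AS_PRINTED,
    endpoints_px: Optional[np.ndarray] = None,
) -> float:
    """Correct a raw pixel extent for the fish-eye (wide-FOV) effect.

    Parameters
    ----------
    obj_pixel:
        Raw extent ``Obj_Pixel`` in pixels.
    obj_distance_mm:
        Carried for interface completeness; the implemented corrections
        are purely angular and do not consume it (the published formula
        divides pixels by millimetres, which is dimensionally
        inconsistent — see the module docstring of :mod:`polypcam`).
    mode:
        See :class:`FisheyeMode`.
    endpoints_px:
        Optional (n, 2) array of outline pixel coordinates (the two
        Feret endpoints, or better the full convex hull of the region).
        In ANGULAR mode the points are undistorted individually and the
        corrected extent is their max pairwise distance, which is
        position-correct at any eccentricity; without them the scalar
        radial map r' = f·tan(r/f) is used.

    Returns
    -------
    float
        ``Obj_Pixel_New`` in pixels.
    """
    _require_positive("obj_pixel", obj_pixel)
    mode = FisheyeMode(mode)
    f = camera.focal_length_px
    if mode is FisheyeMode.NONE:
        return float(obj_pixel)
    if camera.fov_ratio <= 0:
        raise ValueError("FOV ratio must be positive")
    if mode is FisheyeMode.AS_PRINTED:
        theta = math.atan(obj_pixel / f)
        return f * theta * camera.fov_ratio
    if mode is FisheyeMode.ANGULAR_EXTENT:
        if endpoints_px is None:
            # on-axis equidistant extent already is f * angular diameter
            return float(obj_pixel)
        return angular_extent_px(np.asarray(endpoints_px, dtype=float), camera)
    # ANGULAR
    if endpoints_px is not None:
        pts = undistort_points(np.asarray(endpoints_px, dtype=float), camera)
        diff = pts[:, None, :] - pts[None, :, :]
        return float(np.sqrt((diff**2).sum(-1).max()))
    theta = obj_pixel / f
    if theta >= math.pi / 2:
        raise ValueError(
            f"extent {obj_pixel:.1f} px spans >= 90 deg under the equidistant model"
        )
    return f * math.tan(theta)


def thickness_corrected_depth(surface_depth_mm: float, obj_radius_mm: float) -> float:
    """Distance to the polyp body: near-surface depth plus polyp radius (mm)."""
    _require_positive("surface_depth_mm", surface_depth_mm)
    if obj_radius_mm < 0 or not np.isfinite(obj_radius_mm):
        raise ValueError(f"obj_radius_mm must be >= 0, got {obj_radius_mm!r}")
    return surface_depth_mm + obj_radius_mm


def thickness_error_pct(surface_depth_mm: float, obj_radius_mm: float) -> float:
    """Relative depth error (%) committed by ignoring polyp thickness.

    With an 8 mm polyp whose near surface sits at 10 mm, the true body
    distance is 14 mm and ignoring the 4 mm radius costs
    100·4/14 ≈ 29%.
    """
    if obj_radius_mm < 0 or not np.isfinite(obj_radius_mm):
        raise ValueError(f"obj_radius_mm must be >= 0, got {obj_radius_mm!r}")
    total = surface_depth_mm + obj_radius_mm
    if total <= 0:
        raise ValueError("surface depth + radius must be positive")
    return 100.0 * obj_radius_mm / total


def measure_polyp(
    detection,
    depth_map,
    camera: CameraModel,
    fisheye_mode: FisheyeMode | str | None = None,
    depth_statistic: str = "min",
    iterate: bool = False,
    max_iterations: int = 10,
    tol_mm: float = 0.01,
) -> SizeEstimate:
    """Run the full sizing chain on one detected polyp.

    Steps: (a) ``Obj_Distance`` = a depth statistic over the detected
    region (default the minimum, i.e. the apex of the polyp — the value
    the thickness correction is premised on); (b) fish-eye correction of
    the pixel extent; (c) initial triangle-similarity size; (d)
    ``Obj_Radius`` = half the current size estimate; (e) final size from
    the thickness-corrected distance.  With ``iterate=True`` steps
    (d)–(e) repeat to a fixed point; the default is the one-shot
    correction.

    Parameters
    ----------
    detection:
        A :class:`polypcam.detection.Detection`.
    depth_map:
        A :class:`polypcam.depth.DepthMap` (values in mm).
    fisheye_mode:
        Defaults to ANGULAR_EXTENT for equidistant cameras and NONE for
        pinhole ones.
    depth_statistic:
        One of ``min, median, mean, center_pixel``.
    """
    from .detection import region_depth  # local import to avoid a cycle

    if fisheye_mode is None:
        fisheye_mode = (
            FisheyeMode.ANGULAR_EXTENT
            if camera.projection is Projection.EQUIDISTANT
            else FisheyeMode.NONE
        )
    fisheye_mode = FisheyeMode(fisheye_mode)

    obj_distance = region_depth(depth_map, detection, statistic=depth_statistic)
    obj_pixel = detection.pixel_extent
    endpoints = getattr(detection, "hull_px", None)
    if endpoints is None:
        endpoints = getattr(detection, "extent_endpoints_px", None)
    fisheye_fallback = False
    try:
        obj_pixel_new = fisheye_correct(
            obj_pixel, obj_distance, camera, mode=fisheye_mode, endpoints_px=endpoints
        )
    except ValueError:
        # detection spans past 90° off-axis: no pinhole equivalent exists,
        # so fall back to the bounded published correction
        if fisheye_mode is not FisheyeMode.ANGULAR:
            raise
        obj_pixel_new = fisheye_correct(
            obj_pixel, obj_distance, camera, mode=FisheyeMode.AS_PRINTED
        )
        fisheye_fallback = True

    size = initial_size(obj_pixel_new, obj_distance, camera)
    size_initial = size
    radius = size / 2.0
    iterations = 0
    n_steps = max_iterations if iterate else 1
    for _ in range(n_steps):
        corrected = thickness_corrected_depth(obj_distance, radius)
        new_size = initial_size(obj_pixel_new, corrected, camera)
        iterations += 1
        if abs(new_size - size) < tol_mm and iterations > 1:
            size = new_size
            break
        size = new_size
        radius = size / 2.0
    # radius reported is the one used in the last Eq-3 evaluation
    radius_used = size_initial / 2.0 if not iterate else radius

    return SizeEstimate(
        obj_pixel=float(obj_pixel),
        obj_distance_mm=float(obj_distance),
        obj_pixel_corrected=float(obj_pixel_new),
        size_initial_mm=float(size_initial),
        obj_radius_mm=float(radius_used),
        size_final_mm=float(size),
        iterations=iterations,
        truncated=bool(getattr(detection, "touches_border", False)),
        fisheye_fallback=fisheye_fallback,
    )
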