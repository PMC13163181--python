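"""Implicit colon/polyp geometry and ray casting.

The colon is a (optionally bent) tube; polyps are quadric primitives
(hemisphere, spherical cap, sphere-on-stalk) unioned onto the wall.
Every primitive exposes a free-space distance (a signed distance to its
surface, positive in the lumen) so scenes can be sphere-marched; the
straight tube and all polyp primitives additionally expose exact
analytic ray intersections, which the renderer prefers: they are faster
and give silhouettes that are exact to machine precision rather than to
the marching tolerance.

Coordinates: the colon axis is the +z axis starting at z = 0; the wall
is the cylinder of radius ``radius_mm`` (bent tubes follow a circular
arc in the xz-plane).  All lengths in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["Tube", "Sphere", "Capsule", "ColonScene", "build_colon"]

_NO_HIT = np.inf


@dataclass(frozen=True)
class Tube:
    """Tubular lumen: straight (curvature 0) or bent along a circular arc.

    ``curvature`` is 1/bend-radius in 1/mm; the arc lies in the
    xz-plane, tangent to +z at the origin, bending towards +x.
    """

    radius_mm: float
    curvature: float = 0.0
    length_mm: float = 200.0

    def __post_init__(self) -> None:
        if not 10.0 <= self.radius_mm <= 40.0:
            raise ValueError(f"tube radius must be within 10-40 mm, got {self.radius_mm}")
        if self.curvature < 0:
            raise ValueError("curvature must be >= 0")
        if self.curvature > 0 and 1.0 / self.curvature <= self.radius_mm:
            raise ValueError("bend radius must exceed the tube radius")

    def axis_distance(self, p: np.ndarray) -> np.ndarray:
        """Distance from points (..., 3) to the tube axis."""
        p = np.asarray(p, dtype=float)
        if self.curvature == 0:
            return np.hypot(p[..., 0], p[..., 1])
        rb = 1.0 / self.curvature
        # axis: circle of radius rb centred at (rb, 0, 0) in the xz-plane
        ring = np.hypot(p[..., 0] - rb, p[..., 2]) - rb
        return np.hypot(ring, p[..., 1])

    def free_distance(self, p: np.ndarray) -> np.ndarray:
        """Signed distance to the wall, positive inside the lumen."""
        return self.radius_mm - self.axis_distance(p)

    def ray_intersect(self, o: np.ndarray, d: np.ndarray) -> Optional[np.ndarray]:
        """First positive hit parameter per ray, or None if not analytic."""
        if self.curvature != 0:
            return None
        ox, oy = o[..., 0], o[..., 1]
        dx, dy = d[..., 0], d[..., 1]
        a = dx**2 + dy**2
        b = 2 * (ox * dx + oy * dy)
        c = ox**2 + oy**2 - self.radius_mm**2
        disc = b**2 - 4 * a * c
        t = np.full(np.broadcast(ox, dx).shape, _NO_HIT)
        ok = (disc >= 0) & (a > 1e-14)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        # origin inside the lumen (c < 0): the forward root is the + one
        t_hit = (-b + sq) / np.where(ok, 2 * a, 1.0)
        valid = ok & (t_hit > 1e-9)
        t[valid] = t_hit[valid]
        return t

    def surface_normal(self, p: np.ndarray) -> np.ndarray:
        """Inward (lumen-facing) unit normal at wall points."""
        p = np.asarray(p, dtype=float)
        if self.curvature == 0:
            n = -np.stack([p[..., 0], p[..., 1], np.zeros_like(p[..., 0])], axis=-1)
        else:
            n = _numeric_gradient(self.free_distance, p)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)

    def wall_point(self, z_mm: float, angle_rad: float) -> np.ndarray:
        """A point on the wall at axial position z and azimuth angle."""
        if self.curvature == 0:
            return np.array(
                [self.radius_mm * math.cos(angle_rad), self.radius_mm * math.sin(angle_rad), z_mm]
            )
        rb = 1.0 / self.curvature
        s = z_mm / rb  # arc parameter
        centre = np.array([rb - rb * math.cos(s), 0.0, rb * math.sin(s)])
        # local frame: radial-out in the bend plane and y
        e_r = np.array([-math.cos(s), 0.0, -math.sin(s)])  # towards the bend centre is -e_r
        e_y = np.array([0.0, 1.0, 0.0])
        return centre + self.radius_mm * (math.cos(angle_rad) * e_r + math.sin(angle_rad) * e_y)

    def inward_normal(self, z_mm: float, angle_rad: float) -> np.ndarray:
        p = self.wall_point(z_mm, angle_rad)
        return self.surface_normal(p)


def _numeric_gradient(fn, p: np.ndarray, h: float = 1e-4) -> np.ndarray:
    g = np.empty_like(p, dtype=float)
    for k in range(3):
        dp = np.zeros(3)
        dp[k] = h
        g[..., k] = (fn(p + dp) - fn(p - dp)) / (2 * h)
    return g


@dataclass(frozen=True)
class Sphere:
    centre: tuple[float, float, float]
    radius_mm: float

    def free_distance(self, p: np.ndarray) -> np.ndarray:
        c = np.asarray(self.centre)
        return np.linalg.norm(p - c, axis=-1) - self.radius_mm

    def ray_intersect(self, o: np.ndarray, d: np.ndarray) -> np.ndarray:
        c = np.asarray(self.centre)
        oc = o - c
        b = 2 * np.sum(oc * d, axis=-1)
        cc = np.sum(oc * oc, axis=-1) - self.radius_mm**2
        disc = b**2 - 4 * cc
        t = np.full(b.shape, _NO_HIT)
        ok = disc >= 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        t0 = (-b - sq) / 2
        t1 = (-b + sq) / 2
        t_hit = np.where(t0 > 1e-9, t0, np.where(t1 > 1e-9, t1, _NO_HIT))
        t[ok] = t_hit[ok]
        return t

    def surface_normal(self, p: np.ndarray) -> np.ndarray:
        n = p - np.asarray(self.centre)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)


@dataclass(frozen=True)
class Capsule:
    """Cylinder with hemispherical ends, from point a to point b."""

    a: tuple[float, float, float]
    b: tuple[float, float, float]
    radius_mm: float

    def free_distance(self, p: np.ndarray) -> np.ndarray:
        a = np.asarray(self.a)
        ab = np.asarray(self.b) - a
        denom = float(ab @ ab)
        t = np.clip(np.sum((p - a) * ab, axis=-1) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
        return np.linalg.norm(p - closest, axis=-1) - self.radius_mm

    def ray_intersect(self, o: np.ndarray, d: np.ndarray) -> np.ndarray:
        # infinite-cylinder solve clipped to the segment, plus end spheres
        a = np.asarray(self.a)
        ab = np.asarray(self.b) - a
        L = np.linalg.norm(ab)
        u = ab / L
        oa = o - a
        d_perp = d - np.sum(d * u, axis=-1, keepdims=True) * u
        o_perp = oa - np.sum(oa * u, axis=-1, keepdims=True) * u
        A = np.sum(d_perp * d_perp, axis=-1)
        B = 2 * np.sum(o_perp * d_perp, axis=-1)
        C = np.sum(o_perp * o_perp, axis=-1) - self.radius_mm**2
        disc = B**2 - 4 * A * C
        t_cyl = np.full(A.shape, _NO_HIT)
        ok = (disc >= 0) & (A > 1e-14)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        for sign in (-1.0, 1.0):
            t_c = (-B + sign * sq) / np.where(ok, 2 * A, 1.0)
            s = np.sum((o + t_c[..., None] * d - a) * u, axis=-1)
            good = ok & (t_c > 1e-9) & (s >= 0) & (s <= L)
            t_cyl = np.where(good & (t_c < t_cyl), t_c, t_cyl)
        t = t_cyl
        for end in (self.a, self.b):
            t_end = Sphere(tuple(end), self.radius_mm).ray_intersect(o, d)
            t = np.minimum(t, t_end)
        return t

    def surface_normal(self, p: np.ndarray) -> np.ndarray:
        a = np.asarray(self.a)
        ab = np.asarray(self.b) - a
        denom = float(ab @ ab)
        t = np.clip(np.sum((p - a) * ab, axis=-1) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
        n = p - closest
        return n / np.linalg.norm(n, axis=-1, keepdims=True)


class ColonScene:
    """A tube plus labelled polyp primitives (label 1 = polyp, 0 = wall).

    ``support_primitives`` are geometry that renders and occludes like
    the wall but is not polyp-labelled — e.g. the stalk of a
    pedunculated polyp, which is not part of its maximum diameter.
    """

    def __init__(
        self,
        tube: Tube,
        polyp_primitives: Optional[list] = None,
        support_primitives: Optional[list] = None,
    ):
        self.tube = tube
        self.polyp_primitives = polyp_primitives or []
        self.support_primitives = support_primitives or []

    def free_distance(self, p: np.ndarray) -> np.ndarray:
        d = self.tube.free_distance(p)
        for prim in self.polyp_primitives + self.support_primitives:
            d = np.minimum(d, prim.free_distance(p))
        return d

    def first_hit(self, o: np.ndarray, d: np.ndarray, t_max: float = 400.0):
        """First surface hit along rays.

        Returns ``(t, label)`` with ``t = inf`` for misses; label 1
        marks polyp surface.  Uses analytic intersections where the
        tube supports them, sphere marching otherwise.
        """
        o = np.asarray(o, dtype=float)
        d = np.asarray(d, dtype=float)
        t_wall = self.tube.ray_intersect(o, d)
        if t_wall is None:
            t_wall = self._march_wall(o, d, t_max)
        # clip the lumen to its open ends
        z_hit = o[..., 2] + t_wall * d[..., 2] if self.tube.curvature == 0 else None
        if z_hit is not None:
            outside = (z_hit < 0) | (z_hit > self.tube.length_mm)
            t_wall = np.where(outside, _NO_HIT, t_wall)
        t_best = t_wall
        label = np.zeros(t_wall.shape, dtype=np.int8)
        for prim in self.support_primitives:
            t_s = prim.ray_intersect(o, d)
            t_best = np.minimum(t_best, t_s)
        for prim in self.polyp_primitives:
            t_p = prim.ray_intersect(o, d)
            closer = t_p < t_best
            t_best = np.where(closer, t_p, t_best)
            label = np.where(closer, 1, label)
        t_best = np.where(t_best > t_max, _NO_HIT, t_best)
        label = np.where(np.isinf(t_best), 0, label)
        return t_best, label

    def _march_wall(self, o: np.ndarray, d: np.ndarray, t_max: float, eps: float = 1e-3, max_steps: int = 256) -> np.ndarray:
        shape = np.broadcast(o[..., 0], d[..., 0]).shape
        t = np.zeros(shape)
        done = np.zeros(shape, dtype=bool)
        hit = np.zeros(shape, dtype=bool)
        for _ in range(max_steps):
            active = ~done
            if not active.any():
                break
            p = o + t[..., None] * d if o.ndim > 1 or True else o
            step = self.tube.free_distance(o + t[..., None] * d)
            newly_hit = active & (step < eps)
            hit |= newly_hit
            done |= newly_hit
            t = np.where(active & ~newly_hit, t + np.maximum(step, eps * 0.5), t)
            done |= t > t_max
        out = np.where(hit, t, _NO_HIT)
        return out

    def hit_points_and_normals(self, o: np.ndarray, d: np.ndarray, t: np.ndarray, label: np.ndarray) -> np.ndarray:
        """Lumen-facing unit normals at hit points (misses get z-hat)."""
        p = o + np.where(np.isfinite(t), t, 0.0)[..., None] * d
        n = self.tube.surface_normal(p)
        for prim in self.support_primitives:
            near = np.abs(prim.free_distance(p)) < 0.05
            n = np.where(near[..., None], prim.surface_normal(p), n)
        for prim in self.polyp_primitives:
            n_p = prim.surface_normal(p)
            n = np.where((label == 1)[..., None], n_p, n)
        return n


def build_colon(radius_mm: float = 20.0, curvature: float = 0.0, length_mm: float = 200.0) -> ColonScene:
    """Construct an empty colon lumen (no polyp)."""
    return ColonScene(Tube(radius_mm=radius_mm, curvature=curvature, length_mm=length_mm))
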