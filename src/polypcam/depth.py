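"""Depth maps and pluggable depth providers.

The sizing pipeline consumes per-pixel distances in millimetres.  In
deployment these come from a learned monocular depth model; here the
provider interface accepts any callable mapping a scene sample to a
:class:`DepthMap`, and two built-in providers stand in for it:

* :func:`perfect_depth` — ground-truth passthrough;
* :class:`NoiseModel` / :func:`noisy_depth` — stochastic perturbations
  of the ground truth whose magnitude can be calibrated to a target
  average relative error (ARE), e.g. the 7.9% ARE that a trained
  encoder–decoder depth network typically achieves on this task.

The default noise kind is a *low-frequency multiplicative lognormal
field*: depth-CNN errors are spatially smooth (neighbouring pixels share
their error) and roughly proportional to depth.  An optional radial
growth term makes the error standard deviation increase towards the
image periphery, emulating the well-documented degradation of monocular
depth predictions at the edge of wide-FOV images.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import ndimage, optimize, stats

__all__ = [
    "DepthMap",
    "NoiseKind",
    "NoiseModel",
    "perfect_depth",
    "noisy_depth",
    "expected_are",
    "calibrate_sigma",
]

#: Sentinel value stored where a ray hit no geometry (background).
BACKGROUND = 0.0


@dataclass
class DepthMap:
    """Per-pixel Euclidean distances (mm) with a validity mask."""

    values_mm: np.ndarray
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values_mm = np.asarray(self.values_mm, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.values_mm) & (self.values_mm > 0)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values_mm.shape:
                raise ValueError("valid mask shape must match depth values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values_mm.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def copy(self) -> "DepthMap":
        return DepthMap(self.values_mm.copy(), self.valid.copy())


class NoiseKind(str, enum.Enum):
    MULTIPLICATIVE_LOGNORMAL = "multiplicative_lognormal"
    ADDITIVE_GAUSSIAN = "additive_gaussian"
    LOW_FREQUENCY_FIELD = "low_frequency_field"


@dataclass
class NoiseModel:
    """Stochastic depth-error model.

    Parameters
    ----------
    kind:
        ``multiplicative_lognormal`` — i.i.d. per-pixel d·exp(ε),
        ε ~ N(0, σ²);  ``low_frequency_field`` — the same marginal but ε
        is a spatially smooth Gaussian field (correlation
        ``correlation_px``);  ``additive_gaussian`` — d + N(0, σ²) mm,
        clamped to stay positive (clamp count recorded on the output).
    sigma:
        Log-scale (multiplicative kinds) or millimetres (additive).
    correlation_px:
        Gaussian correlation length of the low-frequency field.
    radial_growth:
        β ≥ 0: σ at normalised image radius ρ is multiplied by
        (1 + β·ρ²), ρ = 1 at the image corner.  Emulates the peripheral
        degradation of monocular depth predictions under wide-FOV
        lenses.  0 (default) disables it.
    depth_growth:
        γ ≥ 0: σ at true depth d is multiplied by
        (1 + γ·((d − depth_opt_mm)/depth_scale_mm)²) — a U-shaped
        profile emulating a depth network that is most accurate in the
        middle of its working range.  0 (default) disables it.
    """

    kind: NoiseKind = NoiseKind.LOW_FREQUENCY_FIELD
    sigma: float = 0.0
    correlation_px: float = 64.0
    radial_growth: float = 0.0
    depth_growth: float = 0.0
    depth_opt_mm: float = 25.0
    depth_scale_mm: float = 20.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if isinstance(self.kind, str):
            self.kind = NoiseKind(self.kind)
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.radial_growth < 0:
            raise ValueError("radial_growth must be >= 0")
        if self.depth_growth < 0:
            raise ValueError("depth_growth must be >= 0")
        if self.depth_scale_mm <= 0:
            raise ValueError("depth_scale_mm must be > 0")

    def depth_factor(self, depth_mm: np.ndarray) -> np.ndarray:
        """Per-pixel sigma multiplier from the U-shaped depth profile."""
        if self.depth_growth == 0:
            return np.ones_like(np.asarray(depth_mm, dtype=float))
        z = (np.asarray(depth_mm, dtype=float) - self.depth_opt_mm) / self.depth_scale_mm
        return 1.0 + self.depth_growth * z**2


def perfect_depth(sample) -> DepthMap:
    """Ground-truth passthrough provider (zero error by construction)."""
    return sample.depth_gt.copy()


def _radial_profile(shape: tuple[int, int], beta: float) -> np.ndarray:
    """Per-pixel sigma multiplier 1 + β·ρ², ρ normalised to 1 at the corner."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    rho2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)
    return 1.0 + beta * rho2


def _smooth_unit_field(shape: tuple[int, int], corr_px: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian random field with ~N(0,1) marginals and the given correlation length.

    Long correlation lengths are synthesised on a decimated grid and
    bilinearly upsampled — the field is band-limited far below the
    decimated Nyquist, so this is exact to visual precision and much
    faster than filtering at full resolution.
    """
    if corr_px <= 0:
        return rng.standard_normal(shape)
    ds = max(1, int(corr_px // 8))
    small = (max(4, -(-shape[0] // ds)), max(4, -(-shape[1] // ds)))
    white = rng.standard_normal(small)
    smooth = ndimage.gaussian_filter(white, sigma=corr_px / (2.0 * ds), mode="reflect", truncate=3.0)
    sd = smooth.std()
    if sd < 1e-12:  # pathological tiny images
        return rng.standard_normal(shape)
    # standardise per map: without removing the map mean the heavy
    # smoothing leaves a large random offset and the marginal is no
    # longer N(0,1), which would break the ARE calibration
    smooth = (smooth - smooth.mean()) / sd
    if ds == 1:
        return smooth[: shape[0], : shape[1]]
    out = ndimage.zoom(smooth, ds, order=1, grid_mode=True, mode="nearest")
    return out[: shape[0], : shape[1]]


def noisy_depth(depth_gt: DepthMap, model: NoiseModel, rng: Optional[np.random.Generator] = None) -> DepthMap:
    """Perturb a ground-truth depth map according to ``model``.

    Deterministic given ``model.seed`` (or an explicit ``rng``); the
    validity mask is preserved and positivity guaranteed.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    vals = depth_gt.values_mm.copy()
    valid = depth_gt.valid
    if model.sigma == 0:
        return DepthMap(vals, valid.copy())

    shape = vals.shape
    sigma_map = model.sigma * _radial_profile(shape, model.radial_growth)
    if model.depth_growth > 0:
        sigma_map = sigma_map * np.where(valid, model.depth_factor(vals), 1.0)

    if model.kind is NoiseKind.ADDITIVE_GAUSSIAN:
        noise = rng.standard_normal(shape) * sigma_map
        out = vals + noise
        floor = 1e-3
        n_clamped = int(np.sum((out <= floor) & valid))
        out = np.maximum(out, floor)
        dm = DepthMap(np.where(valid, out, vals), valid.copy())
        dm.n_clamped = n_clamped  # type: ignore[attr-defined]
        return dm

    if model.kind is NoiseKind.MULTIPLICATIVE_LOGNORMAL:
        eps = rng.standard_normal(shape) * sigma_map
    else:  # LOW_FREQUENCY_FIELD
        eps = _smooth_unit_field(shape, model.correlation_px, rng) * sigma_map
    out = vals * np.exp(eps)
    return DepthMap(np.where(valid, out, vals), valid.copy())


def expected_are(sigma: float) -> float:
    """Closed-form expected ARE of multiplicative lognormal noise.

    Per-pixel relative error is |exp(ε) − 1| with ε ~ N(0, σ²);
    E|exp(ε) − 1| = exp(σ²/2)·(2Φ(σ) − 1).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return float(np.exp(sigma**2 / 2.0) * (2.0 * stats.norm.cdf(sigma) - 1.0))


def calibrate_sigma(
    target_are: float,
    kind: NoiseKind | str = NoiseKind.LOW_FREQUENCY_FIELD,
    radial_growth: float = 0.0,
    depth_growth: float = 0.0,
    depth_opt_mm: float = 25.0,
    depth_scale_mm: float = 20.0,
    depth_range_mm: tuple[float, float] = (10.0, 50.0),
    shape: tuple[int, int] = (256, 256),
) -> float:
    """Solve for the sigma whose expected ARE equals ``target_are`` (percent).

    Both lognormal kinds share the closed form of :func:`expected_are`;
    with radial or depth growth the whole-image ARE is averaged over the
    sigma profile (uniform image positions and, for the depth profile,
    per-pixel depths uniform over ``depth_range_mm``) before inverting.
    The additive kind has no scale-free ARE (it depends on the depth
    values) and is rejected.
    """
    kind = NoiseKind(kind)
    if not 0 <= target_are < 100:
        raise ValueError(f"target ARE must be in [0, 100)%, got {target_are}")
    if kind is NoiseKind.ADDITIVE_GAUSSIAN:
        raise ValueError("ARE of additive noise depends on the depth scale; calibrate against a scene instead")
    if target_are == 0:
        return 0.0
    t = target_are / 100.0

    if radial_growth == 0:
        profile = np.array([1.0])
    else:
        # coarse grid: the profile is quadratic, 64x64 is ample
        small = (min(shape[0], 64), min(shape[1], 64))
        profile = _radial_profile(small, radial_growth).ravel()
    if depth_growth > 0:
        d = np.linspace(*depth_range_mm, 41)
        z = (d - depth_opt_mm) / depth_scale_mm
        dfac = 1.0 + depth_growth * z**2
        profile = np.outer(profile, dfac).ravel()

    def mean_are(sigma0: float) -> float:
        s = sigma0 * profile
        return float(np.mean(np.exp(s**2 / 2.0) * (2.0 * stats.norm.cdf(s) - 1.0)))

    hi = 3.0
    if mean_are(hi) < t:
        raise ValueError(f"target ARE {target_are}% not attainable with sigma <= {hi}")
    return float(optimize.brentq(lambda s: mean_are(s) - t, 1e-12, hi, xtol=1e-12))


def make_provider(
    name: str,
    target_are_pct: float = 7.9,
    kind: NoiseKind | str = NoiseKind.LOW_FREQUENCY_FIELD,
    correlation_px: float = 64.0,
    radial_growth: float = 0.0,
    depth_growth: float = 0.0,
    seed: Optional[int] = None,
    shape: tuple[int, int] = (256, 256),
) -> Callable:
    """Build a named depth provider: ``perfect`` or ``noisy``.

    The noisy provider draws an independent error realisation per call
    from a generator seeded once, so repeated measurements differ while
    the whole sequence is reproducible.
    """
    if name == "perfect":
        return perfect_depth
    if name == "noisy":
        sigma = calibrate_sigma(
            target_are_pct,
            kind=kind,
            radial_growth=radial_growth,
            depth_growth=depth_growth,
            shape=shape,
        )
        model = NoiseModel(
            kind=kind,
            sigma=sigma,
            correlation_px=correlation_px,
            radial_growth=radial_growth,
            depth_growth=depth_growth,
        )
        rng = np.random.default_rng(seed)

        def provider(sample) -> DepthMap:
            return noisy_depth(sample.depth_gt, model, rng=rng)

        provider.model = model  # type: ignore[attr-defined]
        return provider
    raise ValueError(f"unknown depth provider {name!r}")
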