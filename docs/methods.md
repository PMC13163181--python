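# Methods

## Measurement model

The system estimates polyp size from a single endoscopic view given
three inputs: a per-pixel depth map in millimetres, a polyp region
(here derived from a silhouette mask), and camera intrinsics.  The core
relation is pinhole triangle similarity, size = distance × pixel extent
/ focal length, refined by two corrections.

**Distance statistic.**  `Obj_Distance` is a statistic of the depth map
over the detected region.  The library default is the *minimum* (apex
depth): the thickness correction is premised on the depth reading being
the distance to the polyp's **near surface**, and the region minimum is
that quantity.  Median, mean and centre-pixel statistics are available
(`region_depth`); the detection module's own default is the median for
generic use, but every measurement path in this package passes `min`
explicitly.  With a median statistic the thickness correction
double-counts roughly half the polyp radius and inflates sizes by
~(r/d)·50% — measurable with the simulator in a few lines.

**Fish-eye correction.**  `fisheye_correct` exposes three modes.

* `as_printed` — the published formula read dimensionlessly:
  `f·arctan(p/f)·(FOV_fisheye/FOV_normal)`.  The printed form divides
  pixels by millimetres inside the arctangent; the implemented reading
  is the dimensionally consistent one, and the FOV ratio (170/140 by
  default) acts as a constant gain.  Kept for fidelity; not the
  accuracy-bearing default, since a uniform +21% gain cannot be correct
  for on-axis objects.
* `angular` — the exact equidistant→pinhole point conversion θ = r/f,
  r′ = f·tan θ, applied to the detection outline and reduced to a
  max-pairwise distance.  This is the right tool for *projection
  conversion* (comparing an equidistant image against a pinhole one);
  it is **not** used for sizing, because triangle similarity is a
  near-axis relation and a pinhole-equivalent extent at eccentricity θ
  carries a sec²θ inflation that similarity misreads as size.
* `angular_extent` (default for equidistant cameras) — the angular
  Feret diameter: `f` times the maximum pairwise angle between the view
  rays of the outline points.  The angular metric is
  rotation-invariant, so the measure is position-independent: an object
  of angular diameter 2α yields extent 2fα anywhere in the field, and
  distance × extent / f = d·2α ≈ 2d·sin α recovers the chord to
  second order.

`FOV_normal` (the reference field of view of a non-fish-eye endoscope)
defaults to 140° and is configurable; camera FOV specifications are
treated as *diagonal* fields of view, the endoscope convention, so a
170° lens places the image corner at 85° off-axis.

**Thickness correction.**  `Object_Size_Final = (Obj_Distance +
Obj_Radius)·Obj_Pixel_New/F_Pixel`, with `Obj_Radius` taken as half the
initial size estimate.  The correction is single-pass by default,
matching the one-shot description of the procedure; fixed-point
iteration (radius ← size/2 until sizes move < 0.01 mm, at most 10
rounds) is opt-in and converges whenever the extent-to-focal ratio is
below 2, i.e. whenever the surface depth exceeds the polyp diameter.
Iteration converges to `d·c/(1 − c/2)` (c = extent/f) and overshoots
for spherical targets, which is why one pass is the default.

**Known geometric bias.**  For a sphere of radius r at centre distance
d, the visible silhouette is the tangent circle, whose projected extent
is amplified by 1/√(1 − (r/d)²) relative to a thin object of the same
diameter.  Pushing the exact extent and exact apex depth through the
single-pass chain yields the size ratio

    (√(d² − r²) + r) / (d + r)  ≈  1 − r²/(2d(d + r)),

an irreducible *underestimate* of the method: −0.5% for 4 mm at 25 mm
but −5.1% for 11 mm at 15 mm.  The geometry-oracle acceptance test
documents exactly this envelope: large polyps viewed close violate a 2%
tolerance no matter how perfect the inputs, because the published chain
contains no tangent-geometry inversion.  (An exact spherical inversion
would solve p = 2fr/√((d_min+r)² − r²) for r; that is deliberately not
part of the measurement chain, which implements the method under test.)

## Scene simulator

The simulator stands in for both a virtual 3-D colon environment and a
physical phantom: an analytic colon lumen (straight or arc-bent tube,
radius 10–40 mm, default 20 mm) with polyp primitives unioned onto the
wall — hemispheres (sessile), sphere-on-stalk capsules (pedunculated)
and spherical caps (flat), each constructed to an exact maximum
diameter.  Rendering casts one ray per pixel under pinhole or
equidistant projection; the straight tube and all polyp primitives
intersect analytically (quadratics), bent tubes fall back to sphere
marching, giving silhouettes exact to machine precision at 256×256 in
~35 ms.  Depth is the **Euclidean ray distance** in mm, not z-depth,
matching the lens-to-surface definition of depth distance; misses
(lumen escape) carry a background sentinel and are excluded from all
metrics.  Shading is Lambertian with a headlight at the optical centre
and inverse-square falloff; brightness is a scalar multiplier (sweep
default {0.6, 1.0, 1.4}).

Placement follows the validation vocabulary: nine FOV cells (a 3×3
image partition) and three lens-to-polyp-centre distance bins — near
(sampled 8–15 mm), medium (15–35 mm), far (sampled 35–55 mm; the
protocol only bounds these bins on one side).  `place_camera` solves
the pose exactly: the optical centre is placed on the sphere of the
requested radius around the polyp centre (re-drawing jittered
directions until it falls inside the lumen), and the rotation maps the
target pixel's view ray onto the polyp direction with a random roll.
Sub-pixel silhouette outlines are available by bisection against the
scene geometry (`silhouette_boundary_points`), used by oracle-grade
tests to remove mask quantisation.

What the simulator does **not** emulate: texture, specularity, fluid,
debris, peristalsis, motion blur, and detector failure — detections
here are oracle silhouettes.  Passing tests therefore validate the
*geometry and statistics* of the method, not robustness to real-scene
nuisance factors or detector error.

## Depth providers and noise calibration

Depth comes from a provider mapping a scene sample to a depth map:
ground truth, or a stochastic stand-in for a trained depth network.
The default noise kind is a multiplicative lognormal **low-frequency
field** (correlation length 64 px): depth-CNN errors are spatially
smooth and roughly proportional to depth.  The field is synthesised on
a decimated grid, standardised per map (without standardisation the
heavy smoothing leaves a large random map-mean offset and the marginal
is no longer N(0,1), silently breaking calibration — this is asserted
by test), and scaled by σ.

Per-pixel relative error is |e^ε − 1|, ε ~ N(0, σ²), with expectation
`exp(σ²/2)·(2Φ(σ) − 1)`; `calibrate_sigma` inverts this numerically so
the expected ARE hits a target (7.9% by default, the accuracy class of
a trained encoder–decoder depth model).  Two optional severity
profiles, both off at the model level and enabled in the experiment
harness defaults:

* radial growth, σ(ρ) ∝ 1 + β·ρ² (β = 2; image corner = 3× centre) —
  peripheral degradation of monocular depth under wide-FOV optics;
* a U-shaped depth profile, σ(d) ∝ 1 + γ·((d − 25 mm)/20 mm)² (γ = 1) —
  a network is most accurate mid-working-range; empirically, depth PE
  is lowest at medium distances.

With profiles enabled, calibration averages the closed form over the
profile (uniform image positions; per-pixel depths uniform on
10–50 mm), so the *whole-reference* ARE still equals the target while
centre/medium conditions are locally better and periphery/extremes
worse.

## Agreement statistics

All estimators are implemented directly and cross-checked against
brute-force oracles in the tests (per-pixel loops, explicit ANOVA
sums of squares, textbook formulas, and pingouin for ICC).  Choices the
literature leaves open: CCC uses population (1/n) moments with a
Fisher-z CI via Lin's asymptotic variance; ICC is the single-measure
absolute-agreement form ICC(A,1) with the McGraw–Wong F-based CI, and
negative ANOVA estimates clamp to 0 with a flag; IQRs use
linear-interpolation quantiles and are always reported alongside means;
terminal-digit membership rounds half-away-from-zero to integer mm
(a continuous estimator never lands exactly on 5/10/15); rank tests use
exact enumeration up to n = 25 without ties, the tie-corrected normal
approximation otherwise.  Pixel boxes are 0-based half-open; the Feret
diameter is measured over pixel *corners*, which preserves
bbox ≤ feret ≤ diagonal and halves the quantisation bias against the
true silhouette extent.

## Experiment harness

The harness runs two campaigns at desk scale.  The grid campaign
measures every polyp (default five sessile polyps, 4–11 mm) at all 27
bin × cell conditions, twice per condition, in two sessions (distinct
placement-jitter and noise seeds per session — the software analogue of
repeating the protocol a week later), and reports per-bin, per-cell and
per-(bin × cell) agreement panels plus the between-session ICC.  The
sweep campaign images a 2–16 mm pedunculated/flat roster many times
with varying brightness and position and pools the agreement panel.
The depth-reference comparison emulates a graduated-forceps reading as
the true centre distance quantised to 1 mm — the most conservative
reading of a mechanical reference.  Reports are deterministic functions
of (config, seed).

Problem sizes throughout (5 polyps × 27 conditions × 2 reps × 2
sessions at 256×256; 20-replicate properties; 100-map calibration
checks) are the package's desk-scale defaults; every report schema is
identical at larger scales.

## Limitations

* The geometric bias envelope above: sizes approaching the viewing
  distance are underestimated by design of the published chain.
* Oracle detections and noise-model stand-ins mean results bound the
  method's geometric/statistical behaviour, not its end-to-end clinical
  accuracy with a real detector and depth network.
* The location-optimality property (medium/centre best) holds in
  expectation, but with 20 measurements per cell the margin between the
  centre cell and its in-bin neighbours (~1 PE point) is comparable to
  the sampling error of a cell mean, so the *strict minimum over all
  27 cells* is not achieved in every replicate.
* Bent-tube rendering is slower (marched, not analytic) and polyps are
  placed on straight segments by default.
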