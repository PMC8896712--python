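# Methods

This note documents the geometric model, the numerical choices behind it,
what the synthetic trajectory generators do and do not emulate, and the
known limitations.

## The eye model

The eye is a sphere of radius 12 mm (the anatomical average) with a
pinhole pupil at the scene-ward pole and the fovea at the opposite pole,
positioned above an infinite flat ground plane (z = 0).  World frame:
x right, y forward, z up.

**Orientation (minimal torsion).**  The eye is oriented so the optic axis
passes through the fixated ground point.  Ocular torsion is held at zero,
defined against the horizon: the eye's transverse (equator) axis stays
horizontal and perpendicular to the gaze azimuth, so the orientation is a
yaw to the gaze azimuth followed by a pure pitch.  This frame was chosen
over a "geodesic from a fixed world-forward reference" alternative
because it is equivariant under ground-plane isometries — rotating the
whole scene and observer together leaves every retinal coordinate
unchanged — which a fixed world reference is not.  Its single degenerate
configuration, gaze straight down, is resolved by carrying the equator
direction over from the previous frame's pose (an error on the first
frame).  Torsion dynamics are out of scope; zero torsion is a standard
simplification and any fixed, consistent convention would do for the
features analysed here.

**Projection.**  The pinhole maps each incoming ray to the antipodal
retinal point, so the retinal position of a ground point reduces to the
spherical direction of the ray:

* ρ — eccentricity in degrees of visual angle, the angle between the ray
  and the optic axis; equal to the great-circle distance of the retinal
  point from the fovea.
* θ — polar angle from the transverse equator, stored in the
  *visual-field* convention (upper field at +π/2, right field at 0); the
  180° inversion of the physical retinal image is applied once here.

Ray directions are anchored at the eye *centre* (nodal-point
convention).  This makes the projection exactly independent of the eye
radius — asserted to 1e−9 in the tests — whereas anchoring at the pole
pupil would shift angles by O(radius/distance), about 0.5% at metre-scale
viewing distances.  ρ is computed with `arctan2`, not `arccos`, because
the latter loses half its precision at the fovea and the lost digits
alias into spurious foveal flow.

**Field of view.**  A 60° half-angle cone about the optic axis.  When the
cone's upper edge reaches the horizontal the ground intersection is
unbounded; those rays are clipped at a configurable maximum ground
distance (default 50 m in the geometry layer).

## Retinal flow and its features

Per frame, an evenly spaced ground grid (default 0.25 m spacing, extent
adaptive to cover the field-of-view footprint over the scenario) is
projected to retinal coordinates with stable point ids.  Flow is the
chart displacement of each point between consecutive frames times the
frame rate (deg/s); the first frame's flow is defined to be zero, and
points not visible on the previous frame carry no flow on their first
visible frame.  The scattered flow is interpolated (piecewise-linear,
convex hull only — no extrapolation, since flow is undefined where no
points constrain it) onto a regular grid on the azimuthal-equidistant
chart x = ρ cos θ, y = ρ sin θ (default 1° spacing, ρ ≤ 60°), where
divergence and z-curl are evaluated with central differences (one-sided
at boundaries; exact for fields linear in position, which is what makes
the canonical test fields come out at exactly 2 everywhere).

Two resolution refinements keep the foveal features limited by the
retinal grid rather than by ground sampling, both documented here because
a uniform ground grid is retinally very coarse near the eye (0.25 m at
1 m distance subtends over 10°):

* a fine static disc of ground points (radius 0.6 m, spacing 0.02 m)
  around each static fixation target, plus the target itself as an
  anchor point — during perfect fixation the anchor projects exactly to
  the fovea with exactly zero flow, making the foveal-null invariant
  (|flow| < 1e−6 deg/s) hold without special-casing;
* the divergence-peak location is re-estimated on a fine local chart
  window using the *model-exact* flow: chart nodes are inverse-projected
  to the continuous ground plane and re-projected at the previous frame.
  The divergence hill varies by only ~1e−4 (relative) per degree near its
  top, far below scatter-interpolation noise at any affordable dot
  density, so argmax-of-scatter localisation carries degrees of error
  that this removes.  A quadratic surface fit over a 1.5° neighbourhood
  places the peak sub-node.

**Planar vs spherical calculus.**  Curl and divergence *fields* (used for
the foveal curl, the iso-contour, and ground back-projection) are
computed with planar operators on the chart, mirroring the standard
evenly-spaced-grid practice; the chart's metric distortion vanishes at
the fovea and stays below ~5% at 60°.  The *location* of the divergence
maximum is the one feature where this matters: the chart's tangential
stretching (ρ/sin ρ) displaces the planar-divergence peak off the
velocity line by roughly 10% of the offset angle at eccentricities of
tens of degrees.  The peak is therefore localised on the metric-corrected
surface divergence

    div_S F = ∂F_ρ/∂ρ + cot(ρ) F_ρ + (1/sin ρ) ∂F_θ/∂θ,

whose maximum does lie on the ground projection of the eye's velocity
(verified against an exact-geometry oracle to ~0.05°).  With this, the
velocity-through-max-divergence law holds to better than 1° at the
default 1° grid.

**Sign conventions.**  Curl fields are counter-clockwise-positive on the
visual-field chart.  The *foveal curl feature* is reported with the
opposite (retinal-surface) sign, so that positive values mean the fixated
point lies left of the path (the walker passes to its right) and negative
values mean fixation right — the field-standard reading of the cue.  The
two conventions differ by the mirror flip between the visual field and
the physical retinal surface; published descriptions of this cue
disagree internally about chirality, so the package states its convention
explicitly and keeps it consistent between the generators, the sweep
tables and the tests.  The heading-angle pair is measured at the
eye's ground position: x = signed angle from the ground-projected
velocity to the fixation direction, y = the same construction with the
direction to the max-divergence ground point; both positive when the eye
passes right of the point.

**Iso-contour.**  The divergence level-set through the foveal value is
extracted by marching squares; the connected component nearest the fovea
is kept.  It is reported `closed` with its shoelace area, `open` when it
reaches the field-of-view or data boundary, and `degenerate` when its
enclosed area falls below one grid cell — including the limiting case
where the divergence maximum sits exactly at the fovea and the level set
is a single point.  During a straight approach at eye height 1.25 m and
speed 1.25 m/s sampled at 60 fps, degeneration occurs at declination
45.0°, confirming the one-eye-height geometry; the declination step
between frames (~0.5°) sets the resolution of that reading.

## Focus-of-expansion tracker

Head-centered flow fields are analysed by negating the field (turning the
FoE from a repellor into an attractor), advecting a 20×20 uniform seed
grid with fixed-arc-length midpoint (RK2) steps of 0.25 grid spacings and
bilinear lookups (particles stop on grid exit, at a step budget, or when
trapped near an attractor), and histogramming endpoints into square bins
of 1/20 field width.  Endpoint clusters that straddle a bin edge are
merged by counting everything within one bin radius of the winning bin's
centroid; the FoE is present when that cluster holds at least 50% of the
particles, located at the cluster centroid (sub-bin accuracy).  FoE
displacement between consecutive frames is converted to deg/s by scaling
with (camera field of view / field width) and multiplying by the frame
rate — note the conversion to per-second units is a multiplication by
fps, not a division.

The synthetic head camera is a pinhole aligned with a configurable fixed
orientation (plus an optional yaw rate for pure-rotation cases).  Its
scene is the ground grid plus a static frontal backdrop plane far ahead,
standing in for above-horizon scene structure; without it the flow field
would be empty above the horizon and a forward-heading FoE would sit
outside the data hull.

## VOR-based calibration

A fixed rotation maps raw eye-in-sensor gaze to eye-in-head gaze.  It is
recovered from a head-sweep session (gaze held on a point 1.4 m ahead on
the ground) by minimising the mean distance between gaze/ground
intersections and the known point over intrinsic X-Y-Z Euler angles
(Nelder-Mead from the zero start; the convention is arbitrary but used
consistently by the generator and the fitter).  Rays that do not descend
to the ground are truncated at 10 m and included in the error, which
keeps the cost finite for large misalignments.  With sweeps about at
least two head axes the problem is identifiable: a 5×5×5 grid of true
rotations within ±10° is recovered to 0.1° noiselessly, and to 0.5° per
axis with 0.5° per-axis angular noise on ~500 frames.  Single-axis sweeps
leave the rotation about the gaze axis unobservable and are flagged with
a warning.

## Synthetic trajectory generators

The generators provide the study conditions for every downstream stage:

* **straight approach** — constant velocity (default 1.25 m/s), constant
  eye height (default 1.25 m; configurable — subject eye heights were not
  recorded, this is a plausible adult value), fixation 5 m out at a
  signed lateral offset angle;
* **sinusoid / corkscrew** — straight base path plus vertical or
  horizontal sinusoidal displacement, or both in quadrature;
* **gait-like head oscillation** — a two-harmonic kinematic model:
  vertical velocity at the 2 Hz step frequency with peak magnitude half
  the walking speed, lateral sway at 1 Hz (alternating feet) with peak
  0.15× walking speed, optional random-walk phase jitter under an
  explicit seed.  It targets exactly the two published statistics (2 Hz
  spectral peak, half-speed vertical peak velocity) and does not attempt
  to reproduce full within-step acceleration waveforms — it is a
  statistical stand-in, not a biomechanical model;
* **perturbations** — *slip*: the gaze ray sweeps a stated total visual
  angle uniformly across a window, so the fixated image drifts across
  the fovea in a stated retinal direction (1° over 250 ms = 4 deg/s of
  foveal image motion; the direction parameter names the direction the
  *image* slips, and the fixation snaps back when the window ends);
  *saccade*: the gaze rotates at a stated rate (e.g. 195 deg/s up-left),
  overriding fixation.  During locomotion the measured foveal grid-flow
  speed during a saccade sits slightly below the injected rate because
  the base flow field at the swept eccentricity opposes it — the
  acceptance measurement therefore uses a gentle approach (1 m/s,
  fixation 6 m out) and a short window, where the confound is ~0.5%;
* **calibration sessions** — head-sweep segments (pitch, yaw, diagonal
  sinusoids) with the eye-in-head gaze corrupted by the inverse of a
  known misalignment plus optional per-axis Gaussian angular noise.

All generators are bit-reproducible given identical parameters and seed.

What passing tests on these scenarios do *not* show: behaviour on real
recordings with tracker noise, imperfect fixation beyond the idealised
slip model, irregular terrain (motion parallax from depth structure is
absent — the ground is a perfect plane), binocular geometry, or ocular
torsion.

## Problem sizes and tolerances

Simulations use the sizes that make the quantities measurable without
waste: scenario analyses clip the ground footprint at 15 m (the foveal
features live well inside that range; the geometry layer's default clip
is 50 m), the default retinal grid is 1° over ρ ≤ 60° with a 2° foveal
averaging window, and acceptance simulations run a 3.2 s approach at
60 fps.  Advection uses 600-step budgets; the calibration optimiser runs
Nelder-Mead with 1e−6 step tolerance.  Degenerate inputs are rejected
with named errors (unknown field kinds, sub-3×3 grids, collinear
scatter, non-positive steps, overlapping same-kind perturbation windows,
zero horizontal velocity in heading angles, empty foveal windows).
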