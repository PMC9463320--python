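# Methods

## Camera model and coordinate conventions

The C-arm is modeled as an ideal pinhole camera rotating about a fixed
iso-center. The world frame is right-handed with origin at the iso-center:
+x patient-left, +y patient-posterior (the source-to-detector axis at zero
angulation), +z patient-cranial. The primary angulation (LAO positive)
rotates the imaging chain about +z; the secondary angulation (cranial
positive) rotates about the already-rotated x-axis, i.e. the total rotation
is `Rz(primary) · Rx(secondary)`. Published descriptions of such systems do
not fix a sign/ordering convention, so this one is declared once and every
derived quantity and test follows from it. At zero angulation the source is
at `(0, −SOD, 0)` and the detector center at `(0, SID − SOD, 0)`.

Pixels are 0-based at pixel centers; the detector pixel
`((rows−1)/2, (cols−1)/2)` coincides with the detector origin, which keeps
the frame symmetric and avoids half-pixel drift. Lengths are mm everywhere,
angles degrees at interfaces. A residual table offset can be supplied as a
translation of the iso-center but defaults to zero, since fiducial
registration absorbs it in practice. Detector skew, radial distortion and
gantry sag are out of scope.

The 2D evaluation plane is the plane through the iso-center parallel to the
detector. A 3D point is mapped onto it by central projection through the
source; a pixel by scaling its detector embedding toward the source by
SOD/SID. Both mappings agree for a point and its own projection, so the 2D
error metric is zero exactly when localization reproduces the picked pixel.

## Centerline representation and resampling

A centerline tree is a list of branches (ordered 3D polylines with optional
per-point radii) plus parent attachment links; junction edges connect the
parent point at the attachment index to the child's first point with the
Euclidean gap as edge length (an epsilon floor keeps zero-gap junctions
traversable in the sparse graph).

Resampling walks each polyline placing points exactly `spacing` apart in
chord length, preserving both endpoints (the final segment may be shorter).
Chord-walking rather than arc-length interpolation makes the operation
exactly idempotent — a polyline whose vertices are already uniformly spaced
resamples to itself — which in turn makes the "half the sampling distance"
error bound exact rather than approximate. The default spacing is 0.5 mm:
the sampling distance should be below the projection resolution (typical
fluoroscopy pixels are 0.2–0.4 mm at the detector, 0.15–0.3 mm at the
iso-center), and 0.5 mm caps the sampling contribution to the 3D error at
0.25 mm.

Continuity neighborhoods are *geodesic*: distances are measured along the
tree (Dijkstra on the point graph), crossing junctions through their
attachment edges. Euclidean proximity would defeat the purpose — branches
that superimpose in projection can be Euclidean-near while being far along
the vasculature, and excluding them is exactly what the restriction is for.

File formats: a CSV dialect (`branch_id,x,y,z[,radius]`), a JSON dialect
that also carries parent links, and legacy ASCII VTK polydata polylines
(one cell per branch, optional `Radius` point data). The VTK reader/writer
is a minimal hand-written implementation covering exactly this polyline
subset; VTK polylines cannot represent junction topology, so trees needing
parent links should use CSV/JSON.

## Localization

The localizer evaluates the cross-product objective
`‖(c − s) × (p′ − s)‖²` exactly as written, with `c` and `p′` in X-ray
coordinates and no normalization; its equivalence to the perpendicular
point-to-ray distance argmin is asserted in tests against an independent
brute-force implementation, not substituted into the code. Ties on the
objective are broken by smaller perpendicular distance, then lower
`(branch_id, index)`, making output deterministic.

A result is flagged *ambiguous* when the best point on any **other** branch
comes within 1% (relative, on the objective) of the minimum. Near-ties on
the same branch are adjacent samples and benign. The flag is informative,
not fatal: for superimposed or view-parallel centerlines the method can
fail, and the package detects and reports rather than guesses. The
relative criterion is intentionally strict — a branch at a noticeably
different depth along the ray produces objective ratios well above 1% even
when it superimposes perfectly in the image, so the flag marks genuine
geometric ambiguity rather than mere visual overlap.

Sequential localization restricts each frame's candidates to the geodesic
window (default 10 mm) around the previous result. The window must exceed
the inter-frame device motion and stay below the distance to superimposed
branches; 10 mm is comfortable for fluoroscopy frame rates and typical
pull-through speeds. When an operator-approved initial position is given,
the first frame is likewise restricted to its neighborhood — the init is
the approved previous position, not a hard assignment.

### Error anatomy

For a marker at perpendicular offset `r` from the centerline and a branch
making angle φ with the projection ray, the worst-case localization error
is `r / sin φ`: the offset component along the ray leaves the projection
unchanged, while the lateral component shifts the nearest-point selection
along the branch by up to `r·cot φ`. The usual "error ≤ vessel radius"
statement therefore assumes centerlines roughly perpendicular to the beam —
which is how projection angulations are chosen clinically, precisely
because view-parallel centerlines degrade both human and algorithmic
localization. The synthetic phantom's default branch orientation honors
this (φ ≈ 80–84° to the central ray at identity angulation), so the
radial-offset experiments exercise the bound at the stated scale; tilting
the branch toward the beam degrades accuracy by the 1/sin φ factor, as the
method's geometry dictates.

## Registration and reference reconstruction

Model-to-X-ray registration is least-squares point-set fitting on fiducial
pairs: the Umeyama closed form for rigid and similarity modes (reflections
rejected; three non-collinear pairs suffice and determine a similarity map
exactly), full linear least squares for affine (≥4 non-coplanar pairs).
Three fiducials under-determine a 12-dof affine map, so *similarity* is the
default mode — sound with the minimal marker set while still absorbing a
global scale error. Fiducial registration error is reported per pair and
as mean/std/median/max.

The reference reconstruction is two-view epipolar triangulation: the
midpoint of the common perpendicular between the two back-projection rays,
with the gap length reported as a quality measure. Rays within ~1e-4
degrees of parallel are rejected. Synthetic two-view datasets refuse pose
pairs separated by less than 5° and warn below 30°, the angular distance
used for two-view registration in clinical workflows. Noiseless
triangulation recovers synthetic markers to machine precision, which is
what qualifies it as the ground-truth stand-in for scoring single-view
localization.

## Tracking

Marker tracking is zero-mean normalized cross-correlation of a fixed
template (extracted at the operator-approved initial position) against a
search window around the previous position. Choices that matter:

- **Prefilter.** Frames are Gaussian-smoothed (σ = 1 px by default) before
  correlation. An un-smoothed noisy template correlates with noise in the
  window and produces occasional 1–2 px peak jitter; matched-scale
  smoothing suppresses it at negligible cost to peak sharpness.
- **Template size** should match the marker footprint (≈ 4σ of the blob).
  Oversized templates add noise-noise correlation variance without signal.
- **Search radius** (default 20 px) should cover inter-frame motion but not
  much more; tight radii suppress gross noise-peak outliers.
- **Sub-pixel refinement** (3-point parabolic, off by default) includes a
  phase correction: the template is extracted on the integer grid, so the
  initial position's fractional part is stored and added back to reported
  positions. Without it every tracked position inherits a constant bias of
  up to half a pixel in each axis.
- Ties on the correlation score go to the smallest displacement; a
  zero-variance search window raises a tracking-lost error, and the
  composed track-and-localize pipeline returns partial results plus an
  explicit status instead of guessing.
- An optional exponential template update (α) exists but is off by default:
  fixed templates cannot drift and are reproducible.

## Synthetic phantom

The generator is the package's test surface and defines its study
conditions. It builds an aortic-arch-like circular arc (radius 35 mm, span
180°, plane tilted 20°) with a straight carotid-like branch (length 80 mm,
radius 3.2 mm — the common carotid's expected intrinsic-error scale) leaving
the arch at a parameterized position, 25° out of the arch plane, oriented
detector-ward so the branch runs nearly perpendicular to the central ray at
identity angulation (see *Error anatomy*). Native sampling is 0.25 mm.
Markers sit at stated arc positions along the branch, displaced radially by
a stated offset in a per-marker seeded random azimuth, so repeated seeds
cover worst-case offset directions. Projection adds optional seeded
Gaussian pixel noise (manual-picking error) and integer quantization.
Rendered sequences are Gaussian blobs (σ = 2 px, amplitude 1) plus seeded
Gaussian noise; SNR is amplitude over noise σ. Acquisition defaults are
TAVR-plausible: SOD 750 mm, SID 1000 mm, 512×512 detector at 0.37 mm/px.

The superimposed-branch scene used for the continuity experiments is a
Y-tree: a short trunk, the true branch, and a decoy branch 40 mm deeper
along the viewing axis constructed as the true branch's perspective-scaled
copy — every back-projection ray of a true-branch point passes through the
decoy curve exactly. The decoy is sampled five times more finely, so once
integer quantization perturbs the picked pixels the unconstrained argmin
jumps to the decoy for roughly half the points, while the 10 mm geodesic
window (the decoy is ≥ 48 mm away along the tree) keeps the constrained
sequence entirely on the true branch. The scene is fully deterministic.

What the generator does **not** emulate: X-ray physics (scatter, beam
hardening, heel effect), anatomical deformation between CT and the
procedure, cardiac/respiratory motion, background clutter from other
devices or bones, and registration error from real two-view workflows.
Passing tests therefore demonstrate the geometric correctness and internal
error budget of the method, not its clinical accuracy; the tracking results
in particular are for clean single-blob scenes.

## Problem sizes and numerics

The randomized oracle comparison uses 1000 scenes (two branches of 40–120
points each, poses spanning ±90° primary / ±40° secondary); recovery
experiments use 8 markers × 10 seeds (on-centerline) and 5 markers × 50
seeds (radial offset); registration noise uses 200 draws at σ = 0.3 mm;
tracking uses 20 seeded 60-frame sequences. These sizes give stable
statistics while keeping the whole suite and the acceptance script in the
tens of seconds on one CPU.

Numerical tie-breaks and degenerate-input behavior are specified everywhere
rather than left to float accidents: exact-equality objective ties resolve
by perpendicular distance then index; triangulation and projection raise
typed errors for near-parallel rays and non-positive depth; junction edges
carry a 1e-12 floor; neighborhood membership uses a 1e-9-scaled boundary
tolerance that absorbs those epsilons; validation errors name the offending
field, row or cell.
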