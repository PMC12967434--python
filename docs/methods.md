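# Methods

This note documents the models, conventions and numerical choices behind
`ulnakin`, and what the synthetic validation does and does not establish
about real dynamic-CT data.

## Coordinate conventions and handedness

All geometry lives in millimetres. The anatomical frame is radius-based
and right-handed: ê_ru (radial→ulnar), ê_pd (palmar→dorsal, dorsal
positive), ê_lon (proximal→distal), with ê_ru × ê_pd = ê_lon. Left wrists
are mirrored once across the sagittal plane into the right-hand
convention before any measurement, so "dorsal positive" signs are uniform
across sides. When no frame is supplied, a geometric surrogate is built
from the data: ê_lon is the radius' dominant principal axis (oriented
distally by a carpal centroid), ê_ru the ulna-ward direction
orthogonalized against it, ê_pd their cross product. The automatic
coordinate systems used on clinical data are typically model-based; this
surrogate reproduces them only up to the accuracy of those two principal
directions, which is why every detector also accepts an externally
supplied frame and landmark set (JSON).

## Landmark detection

* **Distal ulnar articular point.** The most distal ulna vertex marks the
  styloid tip; its local plateau centroid anchors an exclusion cylinder
  (default radius 4 mm — a typical styloid base width — axis parallel to
  ê_lon). The most distal vertex outside the cylinder is the articular
  point. Ties are broken to the lowest vertex index, deterministically.
* **Sigmoid notch.** Per-vertex curvature is computed on the radius
  (below); vertices with concave curvature above 0.1 mm⁻¹ inside a search
  window (distal 25 % of the bone along ê_lon, ulnar half along ê_ru —
  the window suppresses other concave regions and is configurable) are
  classified as notch, and the largest connected component is kept. The
  component is then extended by its bounding *convex* marginal crest
  (adjacent vertices with curvature below −0.1 mm⁻¹): the palmar and
  dorsal margins of the notch are anatomically the convex lips delimiting
  the facet, and the rim of any concavity is convex, so without this
  extension the margins would systematically land one vertex inside the
  rim. The most distal region vertex is the radial reference point for
  ulnar variance; the palmar/dorsal extremes (ties resolved toward the
  notch's longitudinal mid-level) are the margins; the palmar-radial
  corner is the palmar-most distal-rim vertex radial to the notch
  (lexicographic tie-break: palmar, then radial, then distal).
* **Epicentre.** The ulnar longitudinal axis is fitted by principal-axis
  analysis of the proximal 75 % of the bone (shaft only — the head and
  styloid would tilt a whole-bone fit) and intersected with the mesh; the
  most distal intersection is the epicentre.
* **Ulnar head palmar point.** Palmar-most vertex in the distal head
  window (default distal 20 % of the ulna by ê_lon, styloid cylinder
  excluded). Whether the "head" should be the whole distal end or only
  the articular seat is anatomically ambiguous; the window fraction is a
  parameter. With a short scan field of view (the distal forearm only), a
  markedly smaller window can cut above the head's equator and miss the
  true palmar extreme, which is why 20 % is the default.

All detectors are deterministic and equivariant under joint rigid motion
of mesh and frame; landmarks are detected once on the static surfaces and
transported by each bone's per-frame pose, never re-detected per frame.

## Curvature

The default estimator is cotangent-Laplacian mean curvature with mixed
Voronoi vertex areas (exact Voronoi cells on non-obtuse triangles,
half/quarter-area splits at obtuse corners); the mean-curvature normal is
projected on the area-weighted vertex normal to give a signed value.
**Sign convention (fixed): concave regions of the bone surface are
positive**, so the sigmoid notch is positive and a convex sphere of
radius r has curvature −1/r. This makes the 0.1 mm⁻¹ notch threshold
reproducible. On a 10 mm sphere the estimator is accurate to well under
1 % at the mesh resolutions used; boundary vertices of open meshes are
flagged and excluded, never silently included.

A second reading — normal-section curvature along a prescribed direction
(quadric fit of the one-ring in the tangent frame) — is available behind
`curvature(mesh, kind="directional", direction=...)` because the facet's
curvature is dominantly longitudinal and a purely directional definition
is defensible; mean curvature is the default. Both readings detect the
notch on the synthetic wrists.

## Distance engine

Ulnocarpal proximity needs the *exact* surface-to-surface minimum, not a
vertex approximation, because the closest-approach site lies mid-facet at
some wrist positions. `min_distance` computes exact triangle-pair
distances (all vertex–triangle and edge–edge candidates plus an
edge-pierces-triangle test, so interpenetration is exactly 0) over a
candidate set pruned by a vertex KD-tree upper bound, rigorous
per-triangle lower bounds, and axis-aligned-box pair gaps. The exhaustive
all-pairs evaluation is retained as `min_distance_bruteforce` and the two
agree to 1e-9 mm on random meshes. Argument order is canonicalized so the
function is exactly symmetric.

## Registration

Static bones are aligned to each dynamic frame by rigid ICP:
point-to-plane metric when target normals exist (point-to-point Kabsch
otherwise), nearest-neighbour correspondences on a KD-tree, at most 100
iterations, convergence when the RMS residual changes by <1e-4 mm.
Correspondences with residuals above 3× the median are rejected — but
only after 5 warm-up iterations. Early trimming can lock surfaces with
large flat faces into a slid local minimum whose trimmed residual looks
small (observed as a ~4 mm radius slide during simulated forearm
rotation); warm-up preserves the steady-state robustness of trimming
without that failure mode. Frames whose residual exceeds twice the
dynamic-voxel diagonal (voxels 0.59 × 0.59 × 0.50 mm) are flagged.

Bones that are nearly surfaces of revolution (an idealized ulna shaft or
capitate) leave their axial rotation unconstrained under noise; this is a
property of the geometry, not the solver. None of the four parameters
depends on the axial spin of the capitate, and the ulna's landmarks lie
on or near its axis, so the effect on measurements is second-order;
registration accuracy is validated on the radius, whose shape constrains
all six degrees of freedom.

## Parameters and signs

Both DRUJ metrics are axial-view constructions: landmarks are projected
into the plane ⟂ ê_lon before the point–line and point–chord geometry.
This matches how the radioulnar-line and epicentre methods are drawn on
axial slices and gives the exact linear response Δepi = Δmru = −100·t/W
to a dorsal ulnar translation t (a 3-D point-to-line reading would let a
longitudinal offset between the ulnar head and the radius line dilute the
response by a factor ~2 at realistic geometry). Notch width W stays the
3-D chord length. Dorsal dislocation of the radius relative to the ulna
is positive for both metrics: concretely, the value is positive when the
ulnar head point lies palmar to the palmar-radial line (mru) or the
epicentre projects toward the palmar margin (epi).

Wrist angles are signed angles between axis projections in the named
plane of the radius frame: extension, radial deviation and supination
positive. The neutral frame for delta values is the frame of minimum
|wrist angle| (earliest on ties); deltas at the neutral frame are exactly
zero by construction. The ulnar-variance neutral band is |UV| < 1 mm with
the boundaries assigned outward.

## Cohort summaries

One value per wrist per angle bin (that wrist's mean within the bin; an
alternative would pool all frames, which would overweight wrists lingering
in a bin), then median and quartiles across wrists with NumPy's
linear-interpolation quartile rule. Bins visited by fewer than
`min_count` wrists (default 22) are masked; plots draw the median with an
IQR band and dotted vertical lines at the mask edges. Whether a sample is
reported as median/IQR or mean/SD is gated by a Shapiro–Wilk test at
α = 0.05 (median/IQR on rejection, degenerate or out-of-range samples
default to median/IQR with a warning).

## Synthetic wrist generator

The generator is the package's ground-truth instrument, not a fixture
dump: five watertight parametric bones whose landmark positions and
parameter values are known in closed form from the construction.

* Radius: a gridded box with an ellipsoidal concavity carved into the
  ulnar face. The grid lines pass exactly through the notch margins, the
  distal notch apex and the palmar-radial corner, so every radius
  landmark coincides with a mesh vertex; the carve's analytic mean
  curvature (≈0.13–0.15 mm⁻¹ at the pole for the default width 18 mm,
  depth 1 mm) exceeds the 0.1 threshold by construction.
* Ulna: shaft cylinder, spherical head with vertices placed exactly at
  the distal pole, the palmar equator point and along each carpal
  approach direction; a styloid peg whose flat tip has an on-axis centre
  vertex (so tip detection is exact).
* Lunate and triquetrum: spheres whose poles point back along their
  approach directions, so the prescribed ulnocarpal gaps are realized by
  exact vertex pairs; capitate: a capped cylinder along ê_lon.

Static defaults are the neutral medians of a healthy adult cohort:
UV −0.4 mm, UcP-L 3.2 mm, UcP-T 6.9 mm, epicentre centred (0 %). Motion
trajectories sweep neutral → positive extreme → negative extreme →
neutral with amplitudes FE −40…+60°, RUD −25…+10°, PS ±50°, at the
10 frames/s dynamic reconstruction rate; the default 21 frames per sweep
is this package's test problem size. Coupling functions prescribe
ulnar-variance drift, dorso-palmar DRUJ translation (excursions sized to
healthy-cohort epicentre ranges: ≈7.7 %, 9.3 % and 15.2 % of notch width
for FE, RUD, PS) and carpal gap changes relative to each wrist's own
neutral gaps (e.g. strong triquetral approach in ulnar deviation). FE/RUD
rotate the capitate about its centroid; PS rotates radius and carpals
about the ulnar long axis plus the prescribed translations. `degrade`
adds seeded Gaussian jitter and decimation to frame targets only — ground
truth is never touched.

What the generator does **not** emulate: real articular topography (the
lunate fossa, the saddle-shaped triquetrum), cartilage, carpal
intercalation, soft tissue, CT intensity, metal or motion artefacts, and
population shape statistics beyond simple parameter ranges. Passing the
synthetic acceptance therefore shows that the *measurement chain* —
curvature classification, landmark logic, distance engine, registration,
parameter algebra, binning — is correct and numerically tight; it does
not certify landmark accuracy on pathological or highly variant anatomy,
which needs real annotated scans.

## Validation problem sizes

The acceptance computation uses 30 seeded wrists per movement at 11
frames per sweep (noiseless), 50 random mesh pairs (≤200 triangles each)
for the distance oracle, 100 random rigid motions for invariance, and
100 ICP trials at σ = 0.25 mm vertex noise (about half the dynamic voxel
size). Noise robustness of the full pipeline is exercised at the same σ
on a smaller number of seeds in the test suite. These sizes are the
package's validation choices; all are parameters of the underlying
functions.

## Known limitations

* Radius-side landmarking is a geometric surrogate for model-based
  (statistical-shape-model) landmarking; on real bones the palmar-radial
  corner in particular is rounder than any vertex-extreme rule assumes.
  The landmark JSON override exists for exactly this case.
* The curvature threshold (0.1 mm⁻¹) is resolution-dependent on real
  segmentations near the notch lips; the threshold, window and estimator
  kind are all configurable.
* Mesh-level ICP stands in for the image-intensity registration used on
  scanner data; with strong surface noise plus near-symmetric bones the
  axial spin of those bones is unreliable (see Registration).
* Angle-bin summaries assume each wrist's angle trajectory is measured on
  the same convention; mixing sides without mirroring would corrupt the
  signed parameters.
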