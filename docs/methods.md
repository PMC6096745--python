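# Methods

This note documents the models, algorithms, numerical choices and
limitations of `lusplan`.  Everything empirical stated here is computed by
the test suite or by `scripts/acceptance.py`.

## Coordinate conventions

Right-handed coordinates in millimetres.  The CT scan frame is the global
frame; every registration transform maps source (ultrasound / captured
subset) coordinates into CT coordinates.  Transforms act on column vectors,
are stored as rotation matrix + translation vector, and serialise as 4×4
row-major homogeneous matrices.  Landmark lists are paired by index.

## Registration algorithms

**Landmark fit.**  `fit_rigid_landmarks` is the closed-form least-squares
rigid fit: centroid demeaning, SVD of the 3×3 cross-covariance, with the
sign of the last singular direction corrected so the rotation is proper.
Collinear landmark sets are rejected (the rotation about the line is
undetermined); the threshold is a relative 1e-9 on the second singular
value of the demeaned source.  The reported RMS residual is the fiducial
registration error.

**ICP.**  Alternates nearest-neighbour correspondence (k-d tree over all
target points; ties resolve to the lowest index) with a full landmark
re-fit of the source onto its correspondents.  Terminates when the RMS
residual improves by less than `tol` (default 1e-4 mm) or at `max_iter`
(default 200).  The residual sequence is recorded and is non-increasing.

**GO-ICP.**  Branch and bound over SE(3) against the L2 closest-point
objective:

* Both clouds are shifted to their centroids and scaled by a shared factor
  into [−1, 1]³; thresholds are scaled consistently and results mapped back
  to mm.
* Rotation space is the angle-axis ball (radius π unconstrained, or the
  configured half-angle composed with a prior rotation), covered by cubes
  subdivided octree-style.  For a cube of half-width h the per-point
  uncertainty is γ_r(i) = 2·sin(min(√3·h/2, π/2))·‖xᵢ‖.
* Per rotation node, a nested translation branch-and-bound over an
  axis-aligned box (the configured lobe box, else the target bounding box
  plus a 10 mm margin) computes the node's lower bound
  Σ max(dᵢ − γ_r(i) − γ_t, 0)², expanding its frontier in batches so
  nearest-neighbour queries are amortised; capping the inner rounds only
  loosens (never invalidates) the bound.  The translation box constrains
  where the *source centroid* lands in CT space — the practical reading of
  restricting a dataset to the liver lobe it was captured in.
* Upper bounds come from local ICP started at node centres; candidates that
  violate the constraints fall back to the unrefined node-centre pose, so
  the returned transform always satisfies the constraints.
* Termination: the incumbent's mean closest-point distance reaches the
  acceptance threshold (after a configurable minimum number of expanded
  rotation nodes — default 1, the sweep-registration path uses 24, so the
  accepted incumbent is the best over that many explored rotation regions
  rather than the first lucky basin); or the certified gap closes to
  1e-3 mm RMS; or a node budget is exhausted, in which case the result is
  flagged not converged.  The acceptance threshold is the *mean* Euclidean
  closest-point distance (not MSE); the RMS residual is reported alongside.
* Sources larger than 40 points are reduced by farthest-point sampling for
  the search itself; incumbents and the acceptance test always use the
  full source.  With subsampling active the optimality certificate is
  withheld (optimal=False, trivial lower bound), since the bounds refer to
  the subsample.  No trimming or outlier rejection is applied — the full
  L2 objective, as nothing in the application dictates a trimming fraction.
* Exploration order: the queue is ordered by lower bound; ties break by
  insertion order, except in prior-informed registration (the sweep
  pipeline) where they break toward the prior rotation, so the physically
  plausible region enters the incumbent pool within the minimum
  exploration budget.  Planning keeps the bound-driven order: the
  uniqueness decision is *about* which acceptable basin a bound-driven
  search meets first.
* The algorithm is deterministic: no randomness anywhere in the search.

## Feature assessment

Subsets of N bifurcations (N = 3..10, 50 random combinations each at full
scale) are displaced and registered back to the unperturbed model; the
recovered transform applied to *all* bifurcations yields the simulated TRE.
Displacement models: per-point isotropic Gaussians for bifurcation
landmarks (localisation error), one Gaussian vector per branch for
centrelines (inter-branch deformation), σ = 1..5 mm, 200 repetitions per σ
at full scale.  σ is the per-axis standard deviation; the magnitude-vs-axis
ambiguity is resolved this way and fixed.  Bifurcation labels move with the
mean displacement of their adjacent branches.

"Surrounding neighbouring centrelines" for the ICP arm are all branches
with an endpoint within 2× the centreline point spacing of a selected
bifurcation.  ICP starts from the identity (displacements are small);
max 200 iterations, tol 1e-4 mm.

The working radius sorts bifurcations by distance from the centroid of the
picked features and scans outward; it returns the distance of the farthest
bifurcation in the prefix that stays under the 5 mm threshold (0 if the
nearest already violates).  The closed-prefix convention is fixed for
testability; any value up to the first violator's distance would be equally
defensible.

Seed fan-out is counter-based: every (method, N, σ, combination,
repetition) cell derives an independent child stream from the master seed,
so any sub-factorial reproduces bit-for-bit.

## Uniqueness planning

Probe contact positions are sampled from the visible surface vertices by
greedy farthest-point sampling (start index 0, deterministic).  At each
position the radius schedule (5..100 mm step 5 by default) is scanned
ascending; the capture is the closed ball around the position intersected
with the tree's centreline points.  Captures under 10 points are never
unique (a registration of a handful of points is meaningless).  A capture
is unique iff unconstrained GO-ICP with the 2.4 mm mean-distance acceptance
threshold returns an alignment that displaces the captured points by at
most 5 mm on average from their original positions — 5 mm being the
clinical accuracy level used throughout; the framework never defines
"close to the original" more finely than that.  The first success wins
(the paper's "minimum radius" definition); thresholded GO-ICP can in
principle be non-monotone across radii, which the per-sample scan record
makes visible.  Finite sample values are interpolated to all visible
vertices by inverse-distance weighting over the 3 nearest finite samples
(power 1, Euclidean); sentinel samples (never unique) are excluded from
interpolation and encoded −1 on disk.  Geodesic interpolation is out of
scope.

Planning registrations are unconstrained: prior constraints model
knowledge about a real acquisition, which does not exist at planning time.

## Sweep registration

Image-plane convention: mask axes (u, v) map to (x, y) in the probe frame,
frame normal +z, origin at the centre of pixel (0, 0), 0-based indexing;
the per-frame pose carries the calibration.  Vessel sections are
4-connected components; components under 5 pixels are discarded as
segmentation specks.  Component area centroids, scaled by the pixel
spacing and lifted through the pose, form the 3D centreline cloud.

Tracking jitter is suppressed with a smoothing cubic spline
(`make_smoothing_spline`, GCV-chosen regularisation) fitted to the
digitised surface path over frame order; each frame's residual
(raw − spline) is subtracted from that frame's centreline points.  This is
a per-frame displacement correction; re-parameterisation along the path is
deliberately not attempted.

The probe contact position P is the mean of the digitised surface points.
The expanding-radius registration captures the sweep cloud in balls around
P and runs constrained GO-ICP (lobe bounding box + 10 mm margin; prior
sweep direction with a 60° half-angle) against all tree points, recording
the landmark RMS TRE per radius.  The success radius R_S is the smallest
radius whose suffix of defined TREs stays within min·(1+0.10) + 1 mm of
the overall minimum, with at least 2 entries in the stable tail and a
50 mm sanity cap on the minimum itself (failed registrations show large
TRE everywhere).  The reference standard is the direct landmark fit; its
error E_R is a lower bound on any rigid transform's landmark TRE, so
E_R ≤ E_S by construction.  The planning prediction R_U is read at the map
sample nearest the reference probe position P_R, with the distance D_R to
that sample reported as a trust measure.

Insufflated-target experiments need no special code path: they are the
same registration against a different (deformed) target tree.

## Synthetic data

The tree generator grows a binary-bifurcating tree (recursive, randomised
branching angles 25–50°, child length decay 0.72 ± 15 %) inside a
liver-scale ellipsoid (semi-axes 120 × 80 × 60 mm — porcine-liver
magnitude, so the 5–100 mm radius schedule is meaningful).  Branches are
resampled at 2.5 mm spacing, the scale at which centrelines are typically
extracted from abdominal CT.  Depth 6 by default: 31 bifurcations, 63
branches, ≈ 420 centreline points.  Asymmetry is by construction, so
generic subsets have no self-similar twins; binary branching is a
simplification of hepatic anatomy (real trees also trifurcate).

The surface is a spherical-Fibonacci lattice scaled to the ellipsoid with
convex-hull triangulation (watertight by construction); the anterior
(max-z) vertex fraction (40 % by default) is flagged visible.  Visibility
is an input everywhere else in the package, mirroring manual extraction.

Sweep simulation poses frames along a surface path (lateral = x, depth
toward the liver interior = y, sweep direction = z), rasterises the
intersection of 3 mm-radius vessel tubes with each image plane (a pixel is
set iff its centre lies inside a tube; 0.5 mm pixels, 60 × 70 mm field of
view), and digitises the surface with 0.3 mm noise.  Centroid noise
shifts each frame's imaged content in-plane while the stored pose stays
clean — exactly the segmentation/localisation error the extraction then
inherits; pose jitter corrupts the stored poses instead.  Landmark pairs
are bifurcations near the swept volume: the LUS side from the (optionally
deformed) acquisition geometry plus 0.5 mm digitisation noise, the CT side
from the original tree.  Deformation stand-ins: per-branch Gaussian
displacements, or a single-axis squash about the centroid for
insufflation-style compression.  No biomechanics, speckle, or shadowing is
modelled — passing tests therefore show the pipeline's geometric
correctness and its behaviour under idealised noise, not robustness to
real ultrasound artefacts.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` run at reduced scale,
chosen so each stage exercises the same code paths as a full run: the
feature assessment uses N ∈ {3, 6, 10}, σ ∈ {1, 3, 5} mm with 5
combinations × 20 repetitions (100 trials per cell); the uniqueness map
uses 40 surface samples over the full 5–100 mm schedule; sweep experiments
use three clean acquisitions (1 mm centroid noise) over the vessel-dense
core plus one acquisition over the vessel-poor periphery of a tree
deformed with 10 mm per-branch displacements — the constructed failure
case, matching the observation that registration failure coincides with
data far from where planning predicts uniqueness.  The GO-ICP optimality
check compares against an exhaustive oracle (10⁴ rotations × 10³
translations screened through a distance field, best candidates refined by
local ICP) on instances of ≤ 20 source and ≤ 80 target points.

## Known limitations

* Rigid only; deformation appears solely as a data-generating process, and
  the framework's answer to it is failure detection, not correction.
* The uniqueness decision inherits GO-ICP's acceptance threshold: a subset
  judged unique at 2.4 mm mean error may be ambiguous at a stricter one.
* With search subsampling active (sources > 40 points) GO-ICP is a
  certified-bound search on the subsample and a very strong multi-start
  heuristic on the full source; certificates are withheld accordingly.
* Working radius and R_S depend on fixed stability tolerances; both are
  reported with the full curves so other conventions can be recomputed.
* The synthetic liver is an ellipsoid with a binary tree; topology-driven
  ambiguities of real vasculature (near-parallel adjacent branches,
  trifurcations) are only partially represented.
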