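# Methods

## The measurement pipeline

The pipeline mirrors a three-position CT protocol. Inputs are watertight
surface meshes of humerus, ulna and radius in three scan positions
(maximum extension, 90°, maximum flexion), plus humeral landmarks picked in
the 90° scan (medial/lateral epicondyle, a proximal shaft point, the
olecranon tip and the trochlea–capitellum boundary).

1. **Humeral superposition.** The extension- and flexion-scan humeri are
   registered onto the 90° humerus by point-to-point ICP (centroid +
   principal-axes initialization with sign disambiguation by lowest
   nearest-neighbour cost; seeded vertex subsample of 5,000; Kabsch step;
   stop when the RMS change drops below 1e-4 mm or after 100 iterations).
   A result only counts as converged if the final RMS is also below 1 mm —
   same-bone scans of one patient superimpose far more tightly, so a large
   residual means the wrong bone or an unrelated shape was supplied.
2. **Relative forearm motion.** The ulna is registered across scan pairs
   the same way; composing with the humeral corrections expresses its
   motion in the common humeral frame.
3. **Screw axes.** Each relative motion is reduced to its finite helical
   axis: direction and angle from the rotation part, the axis point as the
   least-squares fixed point closest to the origin, pitch as axial
   translation per degree. Motions below 5° of rotation are rejected as
   unreliable (the severely stiff elbow); reconstruction from the axis
   reproduces the motion to 1e-6. The direction sign is canonicalized
   along the mediolateral axis so that +1° means one degree of flexion.
4. **Axis change.** The flexion-axis direction is compared with the
   extension axis by projecting both into the coronal plane
   (span(mediolateral, proximal); signed angle about the anterior normal,
   valgus positive) and the axial plane (span(mediolateral, anterior);
   internal positive). All computation uses the right-elbow convention;
   left elbows are mirrored across the sagittal plane at load time.
5. **Extrapolation and overlap.** Forearm bones are rotated about the
   extension axis from the maximum-extension scan to simulated 0°, and
   about the flexion axis from the maximum-flexion scan to simulated 140°
   (pure rotation by default; the screw pitch is applied if nonzero).
   Extrapolations beyond 90° are refused. The forearm surface is sampled
   (seeded, 8 points/mm² by default), classified against the humerus by
   signed distance, clustered into connected components by sample
   adjacency, and components shallower than the 0.1 mm reporting precision
   are dropped as mesh noise.
6. **Widths.** The default "maximum width" of a component is its maximum
   penetration depth — the deepest unsigned distance from an inside sample
   to the humeral surface, i.e. the resection depth; a maximum-caliper
   extent is available behind `width_method='caliper'` for sensitivity
   analysis. Widths are reported to 0.1 mm, angles to 0.1°. Components are
   assigned to the five regions by partition planes: the sagittal plane
   through the olecranon tip splits posteromedial from posterolateral, the
   trochlea–capitellum boundary plane splits the ulnar from the radial
   side, and the simulated position (0° vs 140°) selects posterior vs
   anterior regions. A single component spanning the olecranon-tip plane
   contributes its medial-side maximum to the posteromedial region and its
   lateral-side maximum to the posterolateral region (the
   continuous-osteophyte rule). Every inside sample belongs to exactly one
   region.
7. **Post-operative residuals.** A post-operative scan (near 90°) is
   aligned by registering its humerus onto the pre-operative reference;
   each forearm bone is then refined onto its pre-operative counterpart
   with *trimmed* ICP (worst 20% of correspondences discarded) so that
   resected regions cannot bias the alignment, and with identity
   initialization since the bone is already nearly in place. The 0°/140°
   overlap measurement is re-run on the post-operative bones about the
   pre-operative axes.

## Geometric queries

Containment and distance queries against watertight meshes are implemented
in `meshquery`: candidate triangles come from a KD-tree over on-face sample
points (each face's centroid and edge midpoints, mapped to their source
face), the exact point-to-triangle distance is minimized over ~12
candidates, and the inside/outside sign is the pseudo-normal of the closest
feature (the sum of face normals over all candidates attaining the
minimum). A slow ray-crossing parity test provides an independent route for
cross-checks. Overlap volumes are integrated on a voxel grid (0.4 mm
default) with each voxel weighted by a linear inside-fraction
`clip(0.5 − sd/pitch, 0, 1)` for both meshes; the linear weighting removes
the O(pitch) grid-phase bias of plain voxel counting at flat interfaces.
Tests compare these volumes against closed forms (spherical cap, sphere
lens) and against a finer 0.2 mm voxelization.

## The synthetic elbow phantom

The phantom exists so every downstream stage can be tested against exact
ground truth. In the humeral frame (x mediolateral, y anterior, z proximal,
extension hinge along +x through the origin):

* the **humerus** is a proximal shaft capsule, a trochlear cylinder and a
  capitellar sphere coaxial with the hinge, a "supracondylar hood" — a
  radial slab spanning the azimuth range (152°–220° from the distal
  direction) that the forearm never visits, whose posterior face acts as
  the olecranon fossa and anterior face as the coronoid/radial fossae —
  and a condylar fill joining these into one body;
* **ulna and radius** are C-shaped wedges hugging the trochlea/capitellum
  (radial clearance 3.5/4 mm) with tapered conical shafts. The wedge faces
  are built to stop 0.25 mm short of the hood faces exactly at the
  simulated terminal poses: the extension-side faces are radial planes
  contacting at 0°, and the flexion-side faces are constructed in the
  140° configuration under the case's perturbed flexion axis and pulled
  back through that motion, so terminal contact stays exact even when the
  flexion axis is tilted.

An osteophyte is a Gaussian bump (height = `size_mm`, FWHM = `footprint_mm`,
default 5 mm) on a wedge face at hinge radius 36 mm: at the blocked
terminal pose its tip penetrates the humeral fossa wall by exactly
`size_mm`. Five bump sites map to the five measurement regions. Heights
are capped at 7.5 mm by the fossa wall margins (beyond that the nearest
humeral surface would no longer be the entry face and the depth reading
would saturate); the generator refuses larger values. Bumps are carried on
the forearm side only: under the penetration-depth definition a bump on the
humeral wall would not measure as its own height, and surgically the
humeral/forearm attribution of an osteophyte is not distinguished anyway.

Two shape choices depart from the simplest possible solids, both forced by
the no-interpenetration invariant over the whole 0–140° arc: the proximal
forearm shafts taper as cones with flank slope tan 5.5° (a constant-radius
shaft's flank would sweep into the anterior fossa wall at deep flexion),
and the hood's radial band (28–46 mm) leaves ≥ 8 mm of wall beyond every
bump tip so the measured depth is always the distance to the entry face.

Meshes are produced by marching cubes on the implicit solids
(`mesh_resolution` = grid pitch = triangle edge target, default 0.6 mm;
the grid origin is offset by an irrational fraction of the pitch so
axis-aligned construction planes never coincide with grid nodes, which
would create degenerate triangles). Marching cubes flattens the Gaussian
bump tip by O(pitch²·h/σ²), which is the dominant width bias: about
−0.1 mm at 0.6 mm pitch and −0.15 mm at 0.7 mm for a 6–7 mm osteophyte.

**Pose model.** Elbow angles are flexion-positive (0 = full extension,
140 = full flexion); clinical extension deficits are the negated values.
Up to 90° the forearm rotates about the extension hinge; beyond 90° about
a flexion axis tilted by (valgus, internal) angles — rotation about the
anterior and proximal axes respectively, both positive per the right-elbow
sign convention. Scan poses add an optional seeded rigid jitter (rotation
and translation SDs set by `rigid_noise_sd`, clipped at 1°/0.5 mm)
modelling patient repositioning between scans.

**Cohort generator.** Per-region widths follow `w = a·ROM + b + ε`
truncated at zero, with per-case seeded substreams so the table is
reproducible independent of case order. Default calibration: ROM from
truncated normals (extension −24 ± 10°, range −45…−5; flexion 119 ± 12°,
range 75…145), flexion-axis shift 0.9 ± 0.4° valgus / 5.2 ± 0.6° internal,
and the five regression lines (slope, intercept, R) of the width-vs-ROM
relations: (−0.16, 2.52, −0.48), (−0.08, 2.16, −0.29), (−0.06, 0.72,
−0.34) against extension and (−0.14, 23.23, −0.45), (−0.08, 11.20, −0.46)
against flexion. The "±" dispersion are treated as SDs with the printed
ranges as truncation bounds. Because truncation at zero attenuates a naive
refit wherever many cases carry no osteophyte (≈19% of radial-fossa widths
are zero under this model), the default generating parameters are solved by
a seeded fixed-point inversion so that the *refit on the truncated data*
reproduces the target slope, intercept and R; passing an explicit
`noise_sd_mm` instead uses the lines literally (the noise-free case then
refits them exactly). Mesh-scene batches (`draw_case_specs`) set each
case's osteophyte sizes to the regression lines evaluated at its ROM
(clipped to the representable range) and redraw ROMs whose arc to the 90°
scan is under 6°, since the three-position protocol cannot extract an axis
from a near-zero arc.

**What the phantom does not emulate.** Real articular geometry (ellipsoid
trochlea grooves, cartilage), CT segmentation error and surface noise,
osteophytes of irregular shape or at other sites, loose bodies, soft-tissue
constraints, and any deformity beyond the rigid flexion-axis tilt. Passing
recovery tests therefore demonstrates the correctness of the measurement
chain on idealized rigid geometry — not clinical accuracy on real CT data.

## Statistics

* **Regression / prediction intervals.** OLS via least squares; r with the
  two-sided t-test p-value; the one-new-observation interval
  `ŷ(x₀) ± t₍n−2,(1+L)/2₎ s √(1 + 1/n + (x₀−x̄)²/Sxx)`, verified against
  statsmodels and by a coverage simulation (`pi_coverage_sim`), which also
  demonstrates under-coverage with heavy-tailed (t₃) noise.
* **Rank tests.** Mid-rank ties throughout. For ≤ 10 total observations
  p-values come from exact enumeration of group assignments (Friedman: of
  within-block orderings, bounded by total cells ≤ 10 since (k!)ⁿ explodes
  otherwise); above that, the normal/χ² approximations. Whether the exact
  route was used is recorded in the result.
* **ICC.** ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n) with
  McGraw–Wong F-based confidence limits; ICC(1,1) = (MSR − MSW)/(MSR +
  (k−1)MSW). Verified against pingouin.
* **A-priori power.** Mann–Whitney sample size by the asymptotic-relative-
  efficiency adjustment of the two-sample noncentral-t calculation (normal
  parent, ARE = 3/π: df and noncentrality scaled by ARE); one-way ANOVA by
  the noncentral F distribution with λ = f²·N, equal groups (total N a
  multiple of k). Defaults α = 0.05, power = 0.80.
* **Multiple comparisons.** Pairwise region comparisons are reported
  uncorrected by default, with an optional Holm adjustment
  (`--holm`); the choice is recorded in the report metadata.

## Problem sizes and numerical choices

The test suite measures 20 full synthetic cases end-to-end at 0.7 mm mesh
pitch and 8 samples/mm² (≈10 s per case), recovering widths with ≤ 0.3 mm
mean absolute error and the axis change within 0.5°. Screw-axis round
trips are checked over 1,000 random motions at 1e-6. The acceptance script
uses 10,000 prediction-interval replicates at n = 92. ICP defaults:
tol 1e-4 mm, 100 iterations, 5,000-point subsample, convergence RMS bound
1 mm, trimming only in the residual pathway (20%). Degenerate inputs error
explicitly: collinear landmark or point sets, non-watertight meshes,
motion arcs < 5°, extrapolation beyond 90°, perturbations beyond ±45°,
hyperextension ROMs, mesh resolution coarser than an osteophyte footprint.
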