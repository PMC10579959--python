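# Methods

## Problem

During atrial-fibrillation ablation, the left atrium (LA) is mapped with an
electro-anatomical mapping (EAM) system, producing a surface anatomy in the
mapping system's coordinate frame. Pre-procedural CT or MRI segmentations of
the same chamber live in a different frame. Fusing the two — so that imaging
features (scar, wall thickness, extra-cardiac structures) can be read on the
mapped anatomy — requires a rigid alignment. `atrialign` implements a fully
automatic two-stage alignment based on iterative closest-point registration
with a point-to-plane metric, together with residual-distance quality
metrics and a synthetic labeled LA phantom that provides ground-truth
transforms for validation.

Only rotation and translation are estimated. Scaling or morphing could mask
genuine anatomical discrepancy (e.g. a different volume state between scan
and procedure), so an imperfect rigid alignment is preferred over a forced
non-rigid one.

## Registration model

Both anatomies are treated as samplings of smooth surfaces rather than sets
of distinctive points. Each ICP iteration:

1. matches every moving (imaging) point to its nearest fixed (EAM) point
   through a k-d tree;
2. rejects matches farther than `rejection_factor` (default 3) times the
   median match distance — robustness against partially mapped anatomies;
3. estimates the rigid update minimising the point-to-plane cost
   `Σ_i [(R p_i + t − q_i)·n_i]²`, where `n_i` is the fixed-surface unit
   normal at the matched point `q_i`.

The normals live on the fixed (EAM) side. For meshes they are area-weighted
averages of incident face normals; for point clouds they come from local
PCA plane fits over `k = 12` nearest neighbours, with signs made globally
consistent by propagation along a minimum spanning tree of the neighbour
graph (edge weight `1 − |n_i·n_j|`) and a final outward-from-centroid flip.
The outward flip assumes a roughly star-shaped chamber, which holds for the
LA body and its tubular appendices.

### The solver

The rotation in the plane cost is linearised as `R ≈ I + [ω]_×`, giving a
6-parameter linear least-squares problem in `(ω, t)`. Because one
linearised step leaves second-order error (≈3×10⁻³ mm² at 3° rotations),
the solver iterates the linearisation on the fixed correspondence set —
Gauss–Newton with step halving — until the cost stops decreasing. The
axis-angle update is exponentiated exactly, so every returned transform is
a true rotation; compositions re-project onto SO(3) via polar
decomposition. On 50 random small-angle instances the converged cost agrees
with a derivative-free 6-parameter minimiser (Powell) to below 10⁻¹⁴ mm².

Rank deficiency — for instance all normals parallel, which leaves in-plane
sliding and rotation undetermined — is handled by minimum-norm least
squares: zero motion along unconstrained directions. The minimum-norm
solution is *accepted* only when it explains the residuals exactly (a plane
displaced purely along its own normal); otherwise the solver raises, since
the remaining misfit would be attributed arbitrarily.

### Iteration control

Accepted per-iteration RMSE is non-increasing: a step whose re-matched RMSE
rises is discarded and retried at half length (because the correspondence
set changes between iterations, a full step can overshoot even when the
direction is good); the loop terminates when no damped step improves.
Convergence is a
relative RMSE change below `1e-4` (stage 1 default), with a cap of 50
iterations. Initialisation is centroid translation by default;
`centroid_pca` (principal axes, sign ambiguity resolved by picking the
proper rotation with lowest initial nearest-neighbour RMSE among the four
candidates) is available for anatomies in arbitrary frames. On noiseless
phantoms the measured capture range of centroid initialisation exceeds 40°
of rotation and 10 mm of translation.

## Two-stage strategy

Stage 1 registers the *full* anatomies: the pulmonary veins (PVs), the
appendage (LAA) and the mitral annulus are the most distinctive landmarks
and pull the registration into the correct pose. These same structures,
however, are segmented differently by imaging and mapping systems (how far
into a vein a segmentation reaches is essentially arbitrary), so stage 2
re-runs the ICP on copies with the distinctive structures excluded — from
the imaging side always, from the EAM side too when it carries labels —
initialised exactly at the stage-1 result and capped at **3 iterations** so
that it can only refine, never re-solve, the alignment. The default
excluded set is all six landmark labels (4 PVs, LAA, annulus), matching the
set excluded from the quality metric; the annulus+PVs-only variant is a
configuration away.

On phantom pairs whose PV lengths differ (one side's veins truncated to 60%
length), the stage-2 refinement improves the body-only median residual in
10/10 pairs (mean improvement ≈ 0.12 mm) — *when correspondence rejection
is disabled*. With the default median-factor rejection enabled, the
mismatched vein-tip correspondences are already discarded during stage 1
and the two variants become statistically indistinguishable on phantoms;
the exclusion mechanism and the rejection mechanism are two routes to the
same robustness. The exclusion-benefit experiment therefore disables
rejection in both arms to isolate the mechanism being tested.

## Pass/fail surrogate

A visual acceptance check is replaced by three automatic criteria, checked
in order; the first failure names the reason:

1. body-surface median residual > `fail_median_mm` (default 5 mm, the outer
   quality threshold of the metric) → `median_exceeds_threshold`;
2. stage 1 did not converge → `stage1_not_converged`;
3. stage-2 final RMSE exceeds the stage-1 final RMSE by more than 20% →
   `stage2_rmse_regression`.

Known limitation: for nearly symmetric chambers a grossly rotated but
body-overlapping alignment can pass these checks (the body median stays
small while landmarks are misplaced). A landmark-aware check would catch
this; it is deliberately out of scope of the surrogate, which mirrors the
body-median quality metric.

## Residual-distance metrics

After alignment, quality is the Euclidean distance from each retained
imaging vertex (landmark labels excluded) to the nearest EAM point, with
median, mean and the percentage of retained surface below 2.5 mm and 5 mm.
Defaults: one-directional (imaging → EAM, because exclusion labels live on
the imaging side) and nearest-vertex distance (both clouds are isotropically
sampled, so the vertex/surface difference is bounded by the spacing). A
`surface` mode (exact point-to-triangle distance when the EAM has faces,
never larger than vertex mode) and a `symmetric` mode (reverse distances
pooled into the summary) are available; none is asserted to be the
clinically canonical choice. The cohort statistic "average median" is the
unweighted mean of per-case medians. Per-vertex distances can be exported
as a PLY scalar field (`residual_mm`, sentinel −1 on excluded vertices) for
regional visualisation.

## Isotropic remeshing

Segmentation exports are often non-isotropic: point density varies by
region, which biases nearest-neighbour correspondences. Spacing uniformity
is measured as the coefficient of variation (CV) of nearest-neighbour
distances (edge lengths for meshes). Resampling draws a dense area-uniform
candidate set (barycentric samples on triangles; the points themselves for
clouds) and applies farthest-point sampling, producing a blue-noise
sampling whose mean spacing matches the target (stop radius calibrated to
0.85× the target; spacing CV ≈ 0.10–0.15 on spheres, well under the 0.3
acceptance threshold). Selected points lie on the input surface by
construction, so geometry never moves. Output is a uniformly spaced point
cloud; registration and metrics operate on points. Defaults: 1.5 mm target
spacing (between MRI voxel pitch and EAM inter-point spacing), CV threshold
0.3, maximum surface deviation 0.5 mm.

The pipeline remeshes any input whose spacing CV exceeds 0.4
(`remesh_mode: trigger`); point clouds already sparser than the target
spacing are left untouched, since subsetting cannot densify.
`remesh_mode: imaging` restores imaging-side-only remeshing;
`off` disables it.

## Synthetic phantom

The phantom is a parametric labeled LA at adult scale: an ellipsoidal body
(semi-axes 30/25/22 mm) with a smooth fixed radial bump field
(`body_irregularity` = 0.08, ≈ ±2.5 mm) — real atrial bodies are irregular,
and a perfect ellipsoid would leave body-only registration rotationally
under-constrained — four cylindrical PV stubs (radius 6 mm, length 15 mm)
on the posterior aspect, one blind appendage lobe antero-superiorly, and a
mitral-annulus rim band (3 mm) around an inferior opening (14 mm radius).
All structures are carved/attached consistently, labeled at generation, and
the union is farthest-point sampled at 2 mm target spacing (EAM-like
density; ≈1800 points), deterministic per seed.

`simulate_acquisition` produces the EAM-like counterpart: a known rigid
displacement (ground truth for every test), isotropic Gaussian point noise,
contiguous-patch dropout for partial coverage (unmapped regions are
spatially coherent, not i.i.d.), and label stripping.
`truncate_structures` shortens labeled tubes to emulate segmentation-depth
mismatch between modalities.

What the phantom does **not** emulate: wall-motion/volume-state differences
between scan and procedure, spatially correlated mapping distortion (e.g.
field-scaling effects), catheter-induced deformation, and realistic
segmentation error structure. Passing the phantom suite therefore shows the
algorithm is correct and well-behaved under its stated model, not that
patient-level accuracy matches any particular clinical figure.

### Noise-model prediction

Under the noise model with perfect alignment, the residual at a clean
vertex is the distance to the nearest of its perturbed neighbours. The
package predicts the cohort median by direct Monte-Carlo: sample actual
local neighbourhoods (12 nearest neighbours) of the clean phantom, perturb
every point with the acquisition noise, record the nearest-point distance
(10⁵ draws). No registration is involved, so this is an independent check
of the full pipeline; observed cohort medians agree with the prediction to
1–3% at noise 0.5 and 1.0 mm. An idealised hexagonal-lattice variant is
kept for when no surface is available; it under-predicts by ~10–20% at
high noise because a densest-packing lattice has nearer neighbours than a
blue-noise sampling.

## Numerical choices and degenerate inputs

- Rotations validated orthonormal with det +1 to 1e-9; compositions
  re-orthonormalised by SVD polar projection.
- Correspondence rejection keeps everything when the median distance is 0
  (exact overlap), and errors when fewer than `min_correspondences` (6)
  pairs survive — the non-overlap signal.
- Collinear point neighbourhoods retry normal estimation with doubled k,
  then error; coplanar neighbourhoods are fine (they define the plane).
- Coincident point sets, empty surfaces, empty post-exclusion surfaces, and
  geometrically impossible phantom parameters raise typed exceptions.
- All randomness flows through explicit integer seeds or
  `numpy.random.Generator` instances; no global RNG state. Identical
  inputs and configuration reproduce results bit-identically.

## Problem sizes

Validation experiments use phantoms of ≈1100–1800 points (2–2.5 mm
spacing): 20-seed noiseless recovery cohorts, 10-case noise cohorts per
noise level, 10 mismatched-PV pairs, and 10⁵-draw Monte-Carlo predictions.
At these sizes the full validation completes in well under a minute per
block on a single CPU while leaving every measured margin wide (recovery
errors ~10⁻¹⁴ mm vs a 0.1 mm bound; noise-model agreement 1–3% vs 15%).
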