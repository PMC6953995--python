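# Methods

This note records the scientific and numerical choices behind the
package: the model each stage assumes, the parameters that matter, what
the synthetic data generator does and does not emulate, and the known
limitations.

## Data model

All geometry is in millimetres with 0-based vertex indices. A mesh is
`(points (n×3), trilist (m×3), colors (n×3, optional, each channel in
[0,1]))`. Coordinates are held at 64-bit precision in memory; PLY files
are written with 32-bit float vertex properties (the dialect virtually
every consumer expects), so disk round trips are exact to float32 and
colors to 1/255 per channel. Only per-vertex color is modelled — the
pipeline samples texture at vertex resolution; UV texture atlases are
out of scope.

## Automatic landmarking

Each scan is rendered from a yaw arc of virtual pinhole cameras
(defaults: yaws 0°, ±30°, ±60°, frontal first; 512×512 images; camera
distance 4× the bounding-sphere radius; field of view chosen so the
mesh fills ~¾ of the frame). Rasterization is z-buffered with
perspective-correct barycentric interpolation, so a covered pixel's
XYZ equals the exact ray–triangle intersection point. Colors are
rendered unlit and back faces culled: the XYZ shape image, the
quantity the method consumes, is independent of shading.

A pluggable 2D detector (any callable returning L×2 pixel coordinates
plus confidences in [0,1]) runs per view; detections are lifted to 3D
by bilinear interpolation of the shape image over the covered pixels of
the 4-neighbourhood (a detection whose neighbourhood is entirely
off-surface is masked, never fatal). Per landmark, the composite keeps
the valid candidate of maximal confidence, ties resolved toward the
earlier camera in rig order — hence the frontal-first default: at equal
confidence the least oblique view has the smallest surface footprint
per pixel.

Accuracy is geometry-limited: a pixel at depth z with focal length f
spans z/f millimetres of fronto-parallel surface, divided by the cosine
of the viewing incidence on oblique surfaces. The tests assert recovery
within exactly this one-pixel surface footprint. Occluded landmarks
(confidence 0 in a view) are recovered from other views; a landmark
hidden in every view stays masked.

## Dense correspondence (NICP)

The template is deformed by one 3×4 affine per vertex,
v̂_i = A_i(v_iᵀ,1)ᵀ, minimizing E = E_d + α·E_s + β·E_ℓ (data,
stiffness, landmark terms as in the README). Procedure:

1. Similarity alignment of the template into the scan frame by
   landmark Procrustes (proper rotation, scale allowed).
2. **TPS initialization** (default on): the aligned template is warped
   through a 3D thin-plate spline interpolating the landmark
   correspondences. With a dense annotation this absorbs the
   low-frequency part of the deformation before any closest-point
   search, which is what keeps tangential correspondence drift small
   (≈2% of mean edge length on ground-truthed warps versus ≈4%
   without). Degenerate landmark configurations fall back to the
   similarity alignment alone.
3. Annealing: for each (α, β) in the schedules, inner iterations
   alternate (i) exact closest-point correspondence search, dropping
   pairs farther than `max_correspondence_dist` (default 5× the mean
   template edge length), pairs landing on a target boundary edge, and
   pairs whose normals disagree by more than 60°; (ii) an exact sparse
   least-squares solve (normal equations, sparse LU) for all A_i at
   fixed correspondences. Because the solve is exact, the fixed-
   correspondence energy is non-increasing across every inner solve —
   an invariant the tests check on every registration. Inner loops stop
   when the mean vertex displacement falls below 1e-3 mm or after 10
   iterations.

Defaults (all exposed in `NICPConfig`): stiffness α geometric from 500
to 2 in 10 levels; landmark β geometric from 20 to 2 (landmarks
dominate early and remain a weak tangential anchor late — releasing
them entirely measurably increases drift on smooth regions); γ = 1
(translation vs linear-part weighting in G). Template vertices without
a valid correspondence at the final level populate the `filled_mask`
and are positioned by the stiffness term alone — this is the hole-
filling behaviour: missing scan regions are bridged smoothly.

Closest-point queries are exact (vertex/edge/interior cases): a KD-tree
over target vertices gives an upper bound d0 on the true distance, and
every triangle whose centroid lies within d0 + R_max (R_max the largest
centroid-to-vertex distance) is checked with exact point–triangle
distances — a guaranteed superset of candidates.

The cylindrical-UV + landmark-TPS route is retained as the classical
baseline; it inherits the known distortion of cylindrical flattening in
high-curvature regions and exists for comparison, not production.

## Statistical modelling

Generalized Procrustes alignment iterates align-to-mean (similarity,
proper rotations) until the relative mean change is below 1e-7, at most
100 iterations. The mean is centred at the origin and renormalized each
iteration to the *average centroid size of the inputs* — scale effects
are removed but the collection keeps its millimetre interpretation, so
downstream errors are reportable in mm.

PCA is a thin SVD of the k×3n centred data matrix (the 3n×3n
covariance is never materialized; k ≪ 3n always holds here).
Eigenvalues are sample variances (1/(k−1)); numerically null modes
(below 1e-14 of the leading eigenvalue) are dropped. Eigenvector sign
is fixed by making each column's largest-magnitude entry positive, so
rebuilds are bit-reproducible — this plus timestamp-free HDF5 writing
makes pipeline reruns produce byte-identical model archives.
Truncation is by retained-variance fraction (pipeline default 0.995) or
an explicit component count.

Bespoke models: an ordered rule list routes a demographic record to a
subgroup model with a global fallback. The default grouping is one
model per listed ethnicity plus age-banded models with half-open bins
[0,7), [7,18), [18,50), [50,∞) — the same bins the age-classification
demo uses as classes.

## Pruning

F(α) = Σ α_i²/λ_i (components with eigenvalues below 1e-12 of the
leading one are excluded from both the sum and the degrees of freedom).
The threshold is the χ²_d inverse CDF at p_f (default 0.99). One
prominent note: the formula is implemented with λ_i per component — the
per-component normalization α_i/√λ_i is the only reading under which
the sum is χ²_d distributed.

The build is single-pass: initial PCA on all corresponded shapes,
flag, rebuild once on the survivors. One desk-scale amendment: scores
computed against the *sample* covariance satisfy Σ_i F_i = d(n−1), so
no shape can score much above n−1 and a threshold beyond that has no
detection power. The initial model's dimensionality is therefore capped
at the largest d with θ_f(d, p_f) ≤ (n−1)/3. For cohorts in the
thousands the cap never binds; at n ≈ 50 it is what makes 10σ planted
outliers detectable at all.

## Evaluation

Generalization and specificity distances are mean per-vertex Euclidean
distances in the Procrustes-aligned model frame (each test shape is
similarity-aligned to the model mean first), so trivial pose error does
not count against the model. Scan fitting follows the simple
nearest-vertex protocol: landmark similarity alignment of the model
mean to the scan, nearest-scan-vertex pseudo-correspondences per model
vertex, subspace projection truncated at c components, and per-vertex
errors (scan vertex to nearest fitted vertex) over a radial crop around
the nose tip. The crop radius defaults to 0.45× the inter-outer-eye-
corner distance — landmark-relative, hence resolution- and
size-independent. Note the landmark-subset alignment is not exactly the
subspace's own frame, which leaves a sub-millimetre error floor even
for perfectly representable targets; vertex-to-nearest-vertex (not
point-to-surface) distance is used as the error, with the exact surface
option available through the same spatial index.

Age classification uses projection coefficients as features and a
pluggable fit/predict classifier (tests and examples plug in
scikit-learn's `LinearSVC`); macro precision/recall/F over the four age
bands on a held-out split.

## Synthetic data generator

The base surface is analytic: a half-ellipsoid (semi-axes 60×80×70 mm)
carrying smooth Gaussian bumps for the nose ridge, eye sockets, brow,
mouth groove and chin, parameterized over (s,t) ∈ [−1,1]², bilaterally
symmetric. Templates are regular grids over the domain (side
8·2^resolution + 1; resolution 1 → 289 vertices, the size used
throughout the tests). The annotation has 68 sites — 13 named
anatomical points plus jawline/brow/nose/eye/mouth contour and coverage
sites — mirroring the density of the 68-point annotations that 2D
facial landmarkers produce; all sites are parameter-lattice points, so
they are template vertices at every resolution.

A subject is

    p(s,t) = base(s,t) + offset_group(s,t) + Σ_j c_j·mode_j(s,t),

with modes low-frequency separable cosine fields (unit amplitude,
distinct frequency/direction per mode), coefficients c_j ~ N(0, σ_j²)
(defaults σ = 3, 2, 1.5, 1, 0.8 mm), and per-group smooth offset
fields. Raw scans are produced by evaluating the same analytic surface
at random parameter sites (default 3× the template vertex count —
scanner output is denser than the registration template) triangulated
by Delaunay in the parameter domain, then adding i.i.d. vertex noise
(default 0.2 mm, a typical structured-light capture error), optional
hole punching (triangles within a radius of a random surface point
removed), and a random rigid transform (±10°, ±20 mm). Because the
surface is analytic, ground truth — corresponded meshes on the template
grid, landmark positions, true coefficients — is exact by construction.
Ages are uniform within each group's range, gender 48% male. When
`age_coupling` is set, mode 1 follows age linearly and mode 2
quadratically; the (linear, quadratic) pair traces a convex curve in
coefficient space, so contiguous age bands are linearly separable by
construction — the separable fixture for the classification demo.
Outlier planting displaces chosen subjects along mode 1 by a stated
number of σ, coherently in raw mesh, ground truth and landmarks.

What the generator does *not* emulate: photorealistic texture (colors
are smooth analytic fields), expression or articulation, scanner-
specific artifacts (quad dominant meshing, seam duplication,
topological noise), and non-Gaussian population structure. Passing
tests therefore demonstrate the correctness and calibration of the
machinery under the stated statistical assumptions, not performance on
any real archive.

## Pipeline

Stages run per subject with failures logged and recorded in the
manifest (reason-coded), never fatal; fewer than 3 surviving subjects
aborts. Stage-2 registrations are cached keyed by a content hash of
mesh bytes, landmarks, template and registration config; the cached
float32 PLY is the canonical artifact (fresh runs read their own cache
back), so fresh and resumed runs build byte-identical archives.

## Problem sizes

The test-suite and acceptance-script populations use template
resolution 1 (289 vertices), raw scans of ~900–12000 vertices, and
cohorts of 40–205 subjects — sizes chosen so the entire battery,
including a full 50-subject pipeline run, completes in a few minutes on
one CPU while leaving every statistical mechanism (calibration,
masking, subspace estimation error) genuinely at play.

## Known limitations

- NICP correspondence quality depends on annotation density; with
  sparse landmarks (≲15) tangential drift on featureless regions
  reaches ~10% of the edge length.
- The chi-square pruning is single-pass and assumes the inlier bulk
  dominates; heavy contamination (≫5%) at small n will mask outliers
  regardless of the power cap.
- The UV route cannot represent surfaces that fold over the cylinder
  (ears, nostril interiors) and is provided only as a baseline.
- Rendering has no lighting model and no anti-aliasing; detectors that
  rely on shading cues would need externally rendered views.
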