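# morphable

Construction and evaluation of 3D statistical shape/texture models
("morphable models") of anatomical surfaces from collections of raw
triangle meshes — built for morphometrics work where scans arrive with
arbitrary topology, capture noise, holes and no manual annotation.

The package implements the full automated pipeline:

1. **Automatic landmarking** — each scan is rendered from a rig of
   virtual perspective cameras; every rendered view carries per-pixel
   world XYZ, so the output of any pluggable 2D landmark localizer is
   lifted back onto the 3D surface and composited across views by
   confidence.
2. **Dense correspondence** — a template surface is non-rigidly
   registered to every scan with landmark-guided non-rigid ICP (NICP):
   one 3×4 affine transform A_i per template vertex, minimizing

   E(A) = E_d(A) + α·E_s(A) + β·E_ℓ(A),

   where E_d = Σ_i dist²(A_i(v_iᵀ,1)ᵀ, S) pulls deformed vertices onto
   the scan S, E_s = Σ_{(i,j)∈ℰ} ‖(A_i − A_j)G‖²_F (G = diag(1,1,1,γ))
   keeps neighbouring transforms similar, and E_ℓ ties landmarked
   vertices to their annotations. α is annealed from very stiff to
   loose; each inner iteration solves the induced sparse least-squares
   system exactly. A cylindrical-UV thin-plate-spline route is included
   as the classical comparison baseline.
3. **Statistical modelling** — generalized Procrustes alignment, then
   PCA via thin SVD: X* = X̄ + Uα with orthonormal basis U and
   eigenvalues λ_i; projection α = Uᵀ(X − X̄), P(X) = X̄ + UUᵀ(X − X̄);
   per-vertex color transferred barycentrically for texture models;
   demographically bespoke sub-models routed by age band / group.
4. **Automatic pruning** — under the model's Gaussian reading,
   F(α) = Σ_i α_i²/λ_i is χ²_d-distributed; subjects with F above the
   p_f quantile (default 0.99) are registration failures and are
   excluded before the final model build.
5. **Evaluation** — compactness, generalization and specificity curves,
   nearest-vertex scan fitting with a radial crop and cumulative error
   distribution (CED) curves, demographic breakdowns, and an
   age-classification demonstration on model coefficients.

Because real craniofacial archives are private, the package ships a
first-class synthetic population generator (`morphable.fixtures`): an
analytic face-like surface with named landmarks, Gaussian deformation
modes, demographic offsets, capture noise, holes, re-meshing and rigid
jitter — with exact ground truth for every stage.

## Worked example

```python
import numpy as np
from morphable import nicp_register
from morphable.fixtures import (FixtureSpec, DemographicGroup,
                                generate_population, make_template)

template, template_lms = make_template(1)
subject = generate_population(FixtureSpec(
    n_subjects=1, seed=7, noise_sd=0.0,
    demographics=(DemographicGroup("A", 1.0, 0.0),)))[0]
result = nicp_register(template, subject.raw, template_lms,
                       subject.landmarks)
surface = result.per_vertex_distance.mean()
truth = np.linalg.norm(result.deformed_template.points
                       - subject.ground_truth.points, axis=1).mean()
print(f"{surface:.4f} mm to the scan surface, "
      f"{truth:.4f} mm from ground truth")
```

prints

```
0.0621 mm to the scan surface, 0.2784 mm from ground truth
```

— the deformed template lies essentially on the scan (0.06 mm), and its
vertices sit 0.28 mm (≈2% of the template's mean edge length) from the
generator's true corresponded positions, i.e. the registration recovered
the anatomical correspondence, not just the surface.

The `examples/` directory has one short script per capability
(population synthesis, landmarking, correspondence, model building,
pruning, evaluation, full pipeline); each prints the numbers it computes
with a line on what they mean. The `morphable` console script exposes
the same stages as subcommands (`synth`, `landmark`, `register`,
`build-model`, `prune`, `evaluate`, `run`, `report`).

## Documentation

`docs/methods.md` describes the model and procedure assumptions, the
parameters that matter with their defaults and units, what the synthetic
generator does and does not emulate, and the numerical design choices.
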