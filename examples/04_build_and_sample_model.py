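"""Build a PCA shape model and draw novel faces from it.

Corresponded meshes are Procrustes-aligned to strip pose and scale,
then a thin-SVD PCA yields the morphable model: mean shape, orthonormal
basis, per-mode variances.  New shapes are mean + basis @ coefficients,
with coefficients drawn from N(0, lambda_i).
"""

import numpy as np

from morphable import (compactness_curve, generalized_procrustes,
                       sample_random)
from morphable.fixtures import FixtureSpec, generate_population
from morphable.models import build_pca, instance, project

pop = generate_population(FixtureSpec(n_subjects=60, seed=1,
                                      noise_sd=0.1, remesh=False))
aligned, mean_mesh = generalized_procrustes(
    [s.ground_truth for s in pop])
model = build_pca([m.as_vector() for m in aligned],
                  aligned[0].trilist, variance_to_retain=0.995)

print(f"model: {model.n_components} components retain 99.5% of the "
      f"variance of {model.n_training} shapes")
comp = compactness_curve(model)
for c in (1, 3, 5):
    print(f"  {c} component(s) explain {comp.y[c - 1]:5.1f}% of variance")

alpha, vec = sample_random(model, rng=42)
print(f"\nrandom face: coefficients (in sds) "
      f"{np.round(alpha / np.sqrt(model.eigenvalues), 2)}")
coeffs, reconstruction = project(model, aligned[0].as_vector())
err = np.linalg.norm(
    (aligned[0].as_vector() - reconstruction).reshape(-1, 3),
    axis=1).mean()
print(f"projecting a training shape back through the model leaves "
      f"{err:.4f} mm mean per-vertex residual")
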