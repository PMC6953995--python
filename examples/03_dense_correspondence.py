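"""Dense correspondence: landmark-guided non-rigid ICP vs the UV-TPS
baseline.

NICP deforms the template with one 3x4 affine per vertex, annealing a
stiffness weight from near-rigid to loose while landmarks act as a soft
constraint.  The UV route flattens both meshes onto a cylinder and
interpolates the landmark correspondence with a 2D thin-plate spline.
Because the fixture keeps ground truth, both methods can be scored
against the true corresponded positions.
"""

import numpy as np

from morphable import LandmarkSet, nicp_register
from morphable.fixtures import (DemographicGroup, FixtureSpec,
                                generate_population, make_template)
from morphable.uvspace import cylindrical_uv_embed, uv_tps_register

template, template_lms = make_template(1)
subject = generate_population(FixtureSpec(
    n_subjects=1, seed=7, noise_sd=0.0,
    demographics=(DemographicGroup("A", 1.0, 0.0),)))[0]

result = nicp_register(template, subject.raw, template_lms,
                       subject.landmarks)
gt_err = np.linalg.norm(result.deformed_template.points
                        - subject.ground_truth.points, axis=1)
print("NICP:")
print(f"  mean distance to scan surface  "
      f"{result.per_vertex_distance.mean():.4f} mm")
print(f"  mean error vs ground truth     {gt_err.mean():.4f} mm "
      f"({100 * gt_err.mean() / template.mean_edge_length():.1f}% of "
      f"mean edge length)")
print(f"  vertices without a valid correspondence (hole filling): "
      f"{int(result.filled_mask.sum())}")

# UV-TPS baseline in the un-jittered frame
R, t = subject.rigid_rotation, subject.rigid_translation
raw = subject.raw.with_points((subject.raw.points - t) @ R)
lm_pts = (subject.landmarks.points - t) @ R
emb_t = cylindrical_uv_embed(template, resolution=(512, 512))
emb_s = cylindrical_uv_embed(raw, resolution=(512, 512))
lm_uv_target = np.column_stack([np.arctan2(lm_pts[:, 0], lm_pts[:, 2]),
                                lm_pts[:, 1]])
uv_mesh = uv_tps_register(emb_t, emb_s,
                          emb_t.uv[template_lms.template_indices],
                          lm_uv_target)
gt_unjit = (subject.ground_truth.points - t) @ R
uv_err = np.linalg.norm(uv_mesh.points - gt_unjit, axis=1)
print("UV-TPS baseline:")
print(f"  mean error vs ground truth     {np.median(uv_err):.4f} mm "
      "(median; the cylindrical flattening distorts high-curvature "
      "regions,\n   which is why the pipeline uses NICP)")
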