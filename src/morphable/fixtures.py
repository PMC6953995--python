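"""Synthetic face-like mesh populations with full ground truth.

Real craniofacial scan archives are private, so every pipeline stage is
exercised on populations generated here instead.  The base surface is
analytic — a half-ellipsoid carrying smooth bump functions for the nose
ridge, eye sockets, brow, mouth groove and chin — parameterized over
(s, t) ∈ [−1, 1]², with named landmarks at fixed parameter sites.
Because the surface (and every deformation mode) is a closed-form
function of (s, t), a subject can be evaluated on the template's own
grid (the ground-truth corresponded mesh) *and* at arbitrary random
parameter sites (a genuinely re-meshed raw scan), with exact ground
truth retained for correspondence, linear modes, demographics and
landmarks.

Per-subject geometry is

    p(s, t) = base(s, t) + group_offset(s, t) + Σ_j c_j · mode_j(s, t)

with mode coefficients c_j ~ N(0, σ_j²), followed by optional vertex
noise, hole punching, re-meshing and rigid jitter.  All randomness flows
from the single seed in the :class:`FixtureSpec`; identical specs give
bit-identical populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay

from .mesh import DemographicRecord, LandmarkSet, TriangleMesh
from .rendering import RenderedView

# ellipsoid semi-axes (mm): width (x), height (y), depth (z)
_AXES = np.array([60.0, 80.0, 70.0])
_THETA_MAX = np.deg2rad(75.0)
_PHI_MAX = np.deg2rad(75.0)

#: Primary anatomical landmark name -> (s, t) parameter site; all sites
#: are multiples of 1/8 so they coincide with grid vertices at every
#: template resolution.
PRIMARY_LANDMARK_SITES = {
    "nose_tip": (0.0, 0.0),
    "nose_bridge": (0.0, 0.25),
    "eye_inner_l": (-0.25, 0.25), "eye_inner_r": (0.25, 0.25),
    "eye_outer_l": (-0.5, 0.25), "eye_outer_r": (0.5, 0.25),
    "brow_l": (-0.375, 0.5), "brow_r": (0.375, 0.5),
    "mouth_l": (-0.25, -0.5), "mouth_r": (0.25, -0.5),
    "mouth_center": (0.0, -0.5),
    "chin": (0.0, -0.875),
    "forehead": (0.0, 0.75),
}


def _contour_sites() -> dict[str, tuple[float, float]]:
    """Secondary contour sites bringing the annotation to ~68 points.

    2D facial landmarkers output dense 68-point annotations (jawline,
    brow, nose, eye and mouth contours), and that density is what anchors
    the tangential component of the registration between the primary
    anatomical points — so the fixture annotation mirrors it.
    """
    sites: dict[str, tuple[float, float]] = {}
    taken = set(PRIMARY_LANDMARK_SITES.values())

    def add(name: str, s: float, t: float) -> None:
        key = (round(s * 8) / 8, round(t * 8) / 8)
        if key not in taken:
            taken.add(key)
            sites[name] = key

    for i, s in enumerate(np.arange(-1.0, 1.001, 0.125)):
        add(f"jaw_{i:02d}", s, -0.875 * (1.0 - s * s))
    for i, s in enumerate((0.125, 0.25, 0.375, 0.5, 0.625)):
        add(f"brow_l_{i}", -s, 0.5)
        add(f"brow_r_{i}", s, 0.5)
    add("nose_ridge_0", 0.0, 0.375)
    add("nose_ridge_1", 0.0, 0.125)
    for i, s in enumerate(np.arange(-0.25, 0.251, 0.125)):
        add(f"nose_base_{i}", s, -0.125)
    for side, sgn in (("l", -1.0), ("r", 1.0)):
        add(f"eye_top_{side}", sgn * 0.375, 0.375)
        add(f"eye_bottom_{side}", sgn * 0.375, 0.125)
        add(f"temple_{side}", sgn * 0.75, 0.5)
        add(f"cheek_upper_{side}", sgn * 0.625, -0.125)
        add(f"cheek_lower_{side}", sgn * 0.5, -0.375)
    for i, s in enumerate(np.arange(-0.125, 0.126, 0.125)):
        add(f"mouth_top_{i}", s, -0.375)
        add(f"mouth_bottom_{i}", s, -0.625)
    # upper-face / lateral coverage (the fixture surface extends past the
    # brow, unlike photo-landmark layouts, so it carries its own sites)
    for side, sgn in (("l", -1.0), ("r", 1.0)):
        add(f"forehead_{side}", sgn * 0.375, 0.75)
        add(f"crown_{side}", sgn * 0.25, 0.875)
        add(f"temple_high_{side}", sgn * 0.625, 0.625)
        add(f"side_{side}", sgn * 0.875, 0.125)
    return sites


#: Full fixture annotation: primary anatomical points first, then the
#: contour sites (order is stable).
LANDMARK_SITES = {**PRIMARY_LANDMARK_SITES, **_contour_sites()}

_BUMPS = (
    # (amplitude mm, s-center, t-center, s-width, t-width)
    (12.0, 0.0, 0.0, 0.14, 0.28),     # nose ridge
    (-4.0, -0.35, 0.25, 0.14, 0.10),  # left eye socket
    (-4.0, 0.35, 0.25, 0.14, 0.10),   # right eye socket
    (-3.0, 0.0, -0.5, 0.30, 0.07),    # mouth groove
    (3.0, 0.0, 0.5, 0.45, 0.10),      # brow
    (4.0, 0.0, -0.85, 0.18, 0.12),    # chin
)


def _base_surface(s: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Half-ellipsoid plus facial feature bumps along the radial
    direction; symmetric in s."""
    theta = s * _THETA_MAX
    phi = t * _PHI_MAX
    direction = np.stack([np.sin(theta) * np.cos(phi), np.sin(phi),
                          np.cos(theta) * np.cos(phi)], axis=-1)
    pts = direction * _AXES
    bump = np.zeros_like(s, dtype=float)
    for amp, s0, t0, ws, wt in _BUMPS:
        bump = bump + amp * np.exp(-(((s - s0) / ws) ** 2
                                     + ((t - t0) / wt) ** 2))
    return pts + bump[..., None] * direction


def _surface_colors(s: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Smooth skin-like per-vertex color field (band structure gives the
    2D detector seam something to look at)."""
    r = 0.75 + 0.10 * np.cos(2.0 * np.pi * t)
    g = 0.55 + 0.10 * np.cos(3.0 * np.pi * s)
    b = 0.45 + 0.05 * np.sin(2.0 * np.pi * (s + t))
    return np.clip(np.stack([r, g, b], axis=-1), 0.0, 1.0)


def _mode_field(j: int, s: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Unit-amplitude smooth deformation field of mode j (mm per unit
    coefficient).  Low spatial frequencies, distinct per mode."""
    freqs = [(1, 1), (2, 1), (1, 2), (2, 2), (3, 1), (1, 3), (3, 2), (2, 3)]
    axes = np.eye(3)
    fs, ft = freqs[j % len(freqs)]
    scalar = np.cos(0.5 * np.pi * fs * s) * np.cos(0.5 * np.pi * ft * t)
    direction = axes[j % 3] + 0.3 * axes[(j + 1) % 3]
    direction = direction / np.linalg.norm(direction)
    return scalar[..., None] * direction


def _group_offset_field(group_idx: int, s: np.ndarray, t: np.ndarray
                        ) -> np.ndarray:
    """Unit-scale smooth demographic mean-offset field, distinct per
    group index."""
    g = group_idx + 1
    scalar = np.sin(0.5 * np.pi * g * (s + 0.2)) * np.cos(
        0.5 * np.pi * (t - 0.1) * ((g % 3) + 1))
    direction = np.array([np.cos(g), np.sin(g), np.cos(2 * g)])
    direction = direction / np.linalg.norm(direction)
    return scalar[..., None] * direction


@dataclass(frozen=True)
class DemographicGroup:
    label: str
    proportion: float
    offset_scale: float = 0.0   # mm scale of the group mean-offset field
    age_range: tuple[float, float] = (1.0, 80.0)


@dataclass
class FixtureSpec:
    """Study conditions for a synthetic population."""

    n_subjects: int = 50
    resolution: int = 1          # grid side = 8·2^resolution + 1
    mode_sds: tuple[float, ...] = (3.0, 2.0, 1.5, 1.0, 0.8)
    demographics: tuple[DemographicGroup, ...] = (
        DemographicGroup("White", 0.6, 0.0),
        DemographicGroup("Black", 0.2, 1.5),
        DemographicGroup("Chinese", 0.2, 1.5),
    )
    male_fraction: float = 0.48
    noise_sd: float = 0.2        # mm capture noise on raw vertices
    hole_probability: float = 0.0
    hole_radius: float = 10.0    # mm
    remesh: bool = True
    remesh_points: int | None = None  # None -> 3x template vertex count
                                      # (scanner output is denser than the
                                      # registration template)
    rigid_rot_deg: float = 10.0
    rigid_trans_mm: float = 20.0
    age_coupling: float = 0.0    # mm of mode 1 per unit normalized age
    seed: int = 0

    def __post_init__(self) -> None:
        props = [g.proportion for g in self.demographics]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"group proportions sum to {sum(props)}, not 1")
        if any(sd < 0 for sd in self.mode_sds) or self.noise_sd < 0:
            raise ValueError("scales must be non-negative")
        if self.resolution < 0:
            raise ValueError("resolution must be >= 0")


@dataclass
class FixtureSubject:
    """One synthetic subject with complete ground truth."""

    record: DemographicRecord
    raw: TriangleMesh                 # noised/remeshed/holed scan
    ground_truth: TriangleMesh        # template topology, scan frame
    true_coeffs: np.ndarray
    landmarks: LandmarkSet            # on the raw surface, scan frame
    is_planted_outlier: bool = False
    group_index: int = 0
    # parameter-domain bookkeeping used by outlier planting
    params_raw: np.ndarray | None = None       # (n_raw, 2)
    params_template: np.ndarray | None = None  # (n_tmpl, 2)
    rigid_rotation: np.ndarray | None = None
    rigid_translation: np.ndarray | None = None


def _grid(resolution: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_side = 8 * 2 ** resolution + 1
    lin = np.linspace(-1.0, 1.0, n_side)
    ss, tt = np.meshgrid(lin, lin, indexing="ij")
    params = np.column_stack([ss.ravel(), tt.ravel()])
    idx = np.arange(n_side * n_side).reshape(n_side, n_side)
    a, b = idx[:-1, :-1].ravel(), idx[1:, :-1].ravel()
    c, d = idx[:-1, 1:].ravel(), idx[1:, 1:].ravel()
    tris = np.concatenate([np.column_stack([a, b, d]),
                           np.column_stack([a, d, c])])
    return params, tris, lin


def _orient_outward(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Flip all triangles if their mean normal points inward."""
    tv = points[tris]
    normals = np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0])
    outward = tv.mean(axis=1) - points.mean(axis=0)
    if np.einsum("ij,ij->i", normals, outward).sum() < 0:
        tris = tris[:, ::-1]
    return tris


def make_template(resolution: int = 1
                  ) -> tuple[TriangleMesh, LandmarkSet]:
    """Deterministic face-like template with named landmark vertices.

    Grid side is 8·2^resolution + 1, so every landmark parameter site
    (a multiple of 1/8) is a grid vertex at any resolution.
    """
    params, tris, lin = _grid(resolution)
    pts = _base_surface(params[:, 0], params[:, 1])
    tris = _orient_outward(pts, tris)
    mesh = TriangleMesh(points=pts, trilist=tris,
                        colors=_surface_colors(params[:, 0], params[:, 1]))
    n_side = len(lin)
    labels, indices = [], []
    for name, (s0, t0) in LANDMARK_SITES.items():
        i = int(round((s0 + 1.0) / 2.0 * (n_side - 1)))
        j = int(round((t0 + 1.0) / 2.0 * (n_side - 1)))
        labels.append(name)
        indices.append(i * n_side + j)
    indices = np.asarray(indices, np.int64)
    lms = LandmarkSet(labels=labels, points=mesh.points[indices],
                      template_indices=indices)
    return mesh, lms


def _subject_surface(params: np.ndarray, coeffs: np.ndarray,
                     group_idx: int, offset_scale: float) -> np.ndarray:
    s, t = params[:, 0], params[:, 1]
    pts = _base_surface(s, t)
    if offset_scale != 0.0:
        pts = pts + offset_scale * _group_offset_field(group_idx, s, t)
    for j, c in enumerate(coeffs):
        if c != 0.0:
            pts = pts + c * _mode_field(j, s, t)
    return pts


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.uniform(-max_deg, max_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K


def _remesh_params(rng: np.random.Generator, n_points: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Random parameter sites + Delaunay triangulation in the domain."""
    interior = rng.uniform(-1.0, 1.0, size=(n_points, 2))
    # ring of boundary sites keeps the hull covering the full domain
    n_edge = max(8, int(np.sqrt(n_points)))
    e = np.linspace(-1.0, 1.0, n_edge)
    boundary = np.concatenate([
        np.column_stack([e, np.full(n_edge, -1.0)]),
        np.column_stack([e, np.full(n_edge, 1.0)]),
        np.column_stack([np.full(n_edge, -1.0), e]),
        np.column_stack([np.full(n_edge, 1.0), e])])
    params = np.vstack([interior, boundary])
    tris = Delaunay(params).simplices
    return params, tris


def generate_population(spec: FixtureSpec) -> list[FixtureSubject]:
    """Generate the synthetic study population for a spec."""
    rng = np.random.default_rng(spec.seed)
    tmpl_params, tmpl_tris, _ = _grid(spec.resolution)
    tmpl_pts_base = _base_surface(tmpl_params[:, 0], tmpl_params[:, 1])
    tmpl_tris = _orient_outward(tmpl_pts_base, tmpl_tris)
    n_tmpl = len(tmpl_params)
    props = np.array([g.proportion for g in spec.demographics])
    lm_labels = list(LANDMARK_SITES)
    lm_params = np.array([LANDMARK_SITES[k] for k in lm_labels])

    subjects = []
    for i in range(spec.n_subjects):
        gi = int(rng.choice(len(props), p=props))
        group = spec.demographics[gi]
        age = float(rng.uniform(*group.age_range))
        gender = "male" if rng.uniform() < spec.male_fraction else "female"
        record = DemographicRecord(subject_id=f"subject_{i:05d}", age=age,
                                   gender=gender, ethnicity=group.label)
        coeffs = rng.standard_normal(len(spec.mode_sds)) * np.asarray(
            spec.mode_sds)
        if spec.age_coupling != 0.0 and len(coeffs):
            # tie mode 1 monotonically to age (normalized to ~[-1, 1]);
            # mode 2, when present, follows the square — the (linear,
            # quadratic) pair traces a convex curve in coefficient
            # space, so every contiguous age band is linearly separable
            a_norm = (age - 40.0) / 40.0
            coeffs[0] = spec.age_coupling * a_norm
            if len(coeffs) > 1:
                coeffs[1] = spec.age_coupling * a_norm ** 2

        gt_pts = _subject_surface(tmpl_params, coeffs, gi,
                                  group.offset_scale)
        if spec.remesh:
            n_raw = spec.remesh_points or 3 * n_tmpl
            raw_params, raw_tris = _remesh_params(rng, n_raw)
            raw_pts = _subject_surface(raw_params, coeffs, gi,
                                       group.offset_scale)
            raw_tris = _orient_outward(raw_pts, raw_tris)
        else:
            raw_params, raw_tris = tmpl_params.copy(), tmpl_tris.copy()
            raw_pts = gt_pts.copy()
        if spec.noise_sd > 0:
            raw_pts = raw_pts + rng.normal(0.0, spec.noise_sd,
                                           raw_pts.shape)
        if spec.hole_probability > 0 and rng.uniform() < spec.hole_probability:
            center = raw_pts[rng.integers(len(raw_pts))]
            centroids = raw_pts[raw_tris].mean(axis=1)
            keep = np.linalg.norm(centroids - center, axis=1
                                  ) > spec.hole_radius
            if keep.sum() >= 4:  # never punch the whole mesh away
                raw_tris = raw_tris[keep]

        R = _random_rotation(rng, spec.rigid_rot_deg)
        tvec = rng.uniform(-spec.rigid_trans_mm, spec.rigid_trans_mm, 3)
        raw_pts = raw_pts @ R.T + tvec
        gt_pts_frame = gt_pts @ R.T + tvec
        lm_pts = _subject_surface(lm_params, coeffs, gi,
                                  group.offset_scale) @ R.T + tvec

        subjects.append(FixtureSubject(
            record=record,
            raw=TriangleMesh(raw_pts, raw_tris,
                             colors=_surface_colors(raw_params[:, 0],
                                                    raw_params[:, 1])),
            ground_truth=TriangleMesh(gt_pts_frame, tmpl_tris),
            true_coeffs=coeffs,
            landmarks=LandmarkSet(labels=lm_labels, points=lm_pts),
            group_index=gi,
            params_raw=raw_params, params_template=tmpl_params,
            rigid_rotation=R, rigid_translation=tvec))
    return subjects


def plant_outliers(population: list[FixtureSubject], k: int,
                   magnitude_sd: float, mode_sd: float | None = None,
                   rng: np.random.Generator | int = 0
                   ) -> list[FixtureSubject]:
    """Displace k subjects ``magnitude_sd`` standard deviations along
    mode 1 and flag them; the rest are untouched.

    ``mode_sd`` defaults to 3.0 mm, the first entry of the default
    :class:`FixtureSpec` mode scale; pass the population's actual value
    when the spec was customized.
    """
    if k > len(population):
        raise ValueError(f"cannot plant {k} outliers in a population "
                         f"of {len(population)}")
    if k == 0:
        return population
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sd = 3.0 if mode_sd is None else float(mode_sd)
    delta = magnitude_sd * sd
    chosen = rng.choice(len(population), size=k, replace=False)
    for idx in chosen:
        subj = population[idx]
        R = subj.rigid_rotation
        for pts, params in ((subj.raw.points, subj.params_raw),
                            (subj.ground_truth.points,
                             subj.params_template)):
            disp = delta * _mode_field(0, params[:, 0], params[:, 1])
            pts += disp @ R.T
        lm_params = np.array([LANDMARK_SITES[k_] for k_
                              in subj.landmarks.labels])
        subj.landmarks.points += delta * _mode_field(
            0, lm_params[:, 0], lm_params[:, 1]) @ R.T
        subj.true_coeffs = subj.true_coeffs.copy()
        subj.true_coeffs[0] += delta
        subj.is_planted_outlier = True
    return population


def true_mode_matrix(spec: FixtureSpec) -> np.ndarray:
    """(3n, n_modes) matrix of the generator's deformation modes sampled
    on the template grid — the ground-truth subspace for recovery tests."""
    params, _, _ = _grid(spec.resolution)
    cols = [(_mode_field(j, params[:, 0], params[:, 1])).reshape(-1)
            for j in range(len(spec.mode_sds))]
    return np.column_stack(cols)


class ProjectingDetector:
    """Oracle 2D detector: projects known 3D landmarks into each view.

    Confidence is 1 where the landmark's surface point is unoccluded in
    the view's z-buffer (its depth agrees with the rendered depth at the
    projected pixel within ``depth_tol`` mm) and 0 otherwise — mirroring
    how a real detector degrades on self-occluded features.
    """

    def __init__(self, landmarks: LandmarkSet, depth_tol: float = 2.5):
        self.landmarks_3d = landmarks
        self.labels = list(landmarks.labels)
        self.depth_tol = depth_tol

    def __call__(self, view: RenderedView
                 ) -> tuple[np.ndarray, np.ndarray]:
        pixels, z = view.camera.project(self.landmarks_3d.points)
        h, w = view.coverage_mask.shape
        conf = np.zeros(len(pixels))
        for i, ((u, v), zi) in enumerate(zip(pixels, z)):
            if not self.landmarks_3d.valid_mask[i] or zi <= 0:
                continue
            r, c = int(round(v)), int(round(u))
            if not (0 <= r < h and 0 <= c < w):
                continue
            if not view.coverage_mask[r, c]:
                continue
            if view.depth is not None and abs(
                    view.depth[r, c] - zi) > self.depth_tol:
                continue  # something nearer occludes this landmark
            conf[i] = 1.0
        return pixels, conf


def oracle_detector(subject: FixtureSubject,
                    depth_tol: float = 2.5) -> ProjectingDetector:
    """Oracle detector for a fixture subject's ground-truth landmarks."""
    return ProjectingDetector(subject.landmarks, depth_tol=depth_tol)
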