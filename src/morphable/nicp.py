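"""Landmark-guided non-rigid ICP template registration.

The template is deformed by one 3×4 affine transform per vertex,
v̂_i = A_i·(v_iᵀ, 1)ᵀ, chosen to minimize

    E(A) = E_d(A) + α·E_s(A) + β·E_ℓ(A)

where E_d sums squared distances from deformed vertices to the target
surface, E_s penalises the G-weighted Frobenius difference of affine
transforms across template edges (G = diag(1, 1, 1, γ) trades the
translational against the linear part), and E_ℓ ties landmarked template
vertices to their annotated 3D locations.  The stiffness weight α is
annealed over an outer schedule from very stiff (near-global affine) to
loose (local detail); β decays alongside it so landmarks dominate the early
coarse alignment and fall back to a weak tangential anchor once the
surface term takes over.

Each inner iteration fixes correspondences by exact closest-point search
(dropping pairs that are too distant, hit the target boundary, or have
incompatible normals) and then solves the induced sparse linear
least-squares problem in all A_i exactly — so for fixed correspondences
the quadratic energy can never increase across a solve.  Template
vertices without a valid correspondence at the final stiffness level are
positioned by the stiffness term alone, which is what fills holes in the
scan with smoothly interpolated surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .align import procrustes_align
from .mesh import LandmarkSet, TriangleMesh
from .surface import SurfaceIndex

log = logging.getLogger(__name__)


@dataclass
class AffineStack:
    """One 3×4 affine transform per template vertex."""

    transforms: np.ndarray  # (n, 3, 4)

    def __post_init__(self) -> None:
        self.transforms = np.asarray(self.transforms, float)
        if self.transforms.ndim != 3 or self.transforms.shape[1:] != (3, 4):
            raise ValueError("transforms must be (n, 3, 4)")
        if not np.isfinite(self.transforms).all():
            raise ValueError("non-finite affine transform")

    @classmethod
    def identity(cls, n: int) -> "AffineStack":
        t = np.zeros((n, 3, 4))
        t[:, :, :3] = np.eye(3)
        return cls(t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Deform the template points this stack is attached to."""
        homog = np.column_stack([points, np.ones(len(points))])
        return np.einsum("nij,nj->ni", self.transforms, homog)


@dataclass
class NICPConfig:
    """Annealing schedules and correspondence-rejection thresholds.

    ``stiffness_schedule`` must be strictly decreasing; the landmark
    schedule has the same length and decays to a small terminal weight
    (it may end at 0 to fully release the landmarks).
    ``max_correspondence_dist`` defaults to 5× the template's mean edge
    length when left ``None``.
    """

    stiffness_schedule: tuple[float, ...] = tuple(
        float(a) for a in np.geomspace(500.0, 2.0, 10))
    landmark_schedule: tuple[float, ...] = tuple(
        float(b) for b in np.geomspace(20.0, 2.0, 10))
    gamma: float = 1.0
    inner_tolerance: float = 1e-3   # mm mean vertex displacement
    max_inner_iters: int = 10
    normal_compatibility_deg: float = 60.0
    max_correspondence_dist: float | None = None
    #: warp the similarity-aligned template through a 3D thin-plate spline
    #: interpolating the landmark correspondences before the annealing
    #: loop.  With a dense annotation this removes most of the
    #: low-frequency warp up front, so the closest-point data term starts
    #: from nearly correct correspondences and tangential drift stays
    #: small.  Requires >= 5 mutually valid landmarks; degenerate landmark
    #: configurations fall back to the similarity alignment alone.
    tps_initialization: bool = True

    def __post_init__(self) -> None:
        a = np.asarray(self.stiffness_schedule, float)
        b = np.asarray(self.landmark_schedule, float)
        if a.size != b.size:
            raise ValueError("stiffness and landmark schedules must have "
                             "the same length")
        if a.size == 0 or (np.diff(a) >= 0).any() or (a <= 0).any():
            raise ValueError("stiffness schedule must be strictly "
                             "decreasing and positive")
        if (b < 0).any():
            raise ValueError("landmark weights must be non-negative")
        for name in ("gamma", "inner_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_inner_iters < 1:
            raise ValueError("max_inner_iters must be >= 1")
        if (self.max_correspondence_dist is not None
                and self.max_correspondence_dist <= 0):
            raise ValueError("max_correspondence_dist must be positive")


@dataclass
class RegistrationResult:
    """Deformed template plus diagnostics of one registration."""

    deformed_template: TriangleMesh
    transforms: AffineStack
    per_vertex_distance: np.ndarray  # (n,) mm to the target surface
    filled_mask: np.ndarray          # (n,) True where no correspondence held
    final_energy: float
    #: (E_before_solve, E_after_solve) at fixed correspondences, one pair
    #: per inner solve, in execution order.
    inner_energy_pairs: list[tuple[float, float]] = field(default_factory=list)
    #: similarity transform that carried the template into the scan frame;
    #: ``transforms`` act on the aligned (and, when TPS initialization is
    #: enabled, landmark-warped) template.
    initial_alignment: object | None = None


def _edge_structure(template: TriangleMesh, gamma: float) -> sp.csr_matrix:
    """kron(M, G): 4 stiffness rows per template edge."""
    edges = template.edges()
    e = len(edges)
    M = sp.csr_matrix(
        (np.concatenate([np.ones(e), -np.ones(e)]),
         (np.concatenate([np.arange(e), np.arange(e)]),
          np.concatenate([edges[:, 0], edges[:, 1]]))),
        shape=(e, template.n_points))
    G = sp.diags([1.0, 1.0, 1.0, gamma])
    return sp.kron(M, G, format="csr")


def _data_matrix(points: np.ndarray) -> sp.csr_matrix:
    """D: row i is [v_i, 1] placed in block i of the 4n unknown layout."""
    n = len(points)
    cols = (4 * np.arange(n)[:, None] + np.arange(4)[None, :]).ravel()
    rows = np.repeat(np.arange(n), 4)
    vals = np.column_stack([points, np.ones(n)]).ravel()
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, 4 * n))


def nicp_energy(transforms: AffineStack, template: TriangleMesh,
                target: TriangleMesh, landmarks: LandmarkSet,
                config: NICPConfig, alpha: float, beta: float,
                _surface: SurfaceIndex | None = None
                ) -> tuple[float, float, float, float]:
    """Evaluate E, E_d, E_s, E_ℓ of a transform stack.

    E_d uses the exact point-to-surface distance of every deformed
    template vertex; E_s sums G-weighted squared Frobenius differences
    over the template edge set; E_ℓ sums over valid landmarks carrying
    template vertex indices.
    """
    if landmarks.template_indices is None:
        raise ValueError("landmarks must carry template_indices")
    A = transforms.transforms
    if len(A) != template.n_points:
        raise ValueError("one transform per template vertex required")
    deformed = transforms.apply(template.points)
    surf = _surface if _surface is not None else SurfaceIndex(target)
    _, dists, _ = surf.closest_points(deformed)
    e_d = float((dists ** 2).sum())
    edges = template.edges()
    diff = A[edges[:, 0]] - A[edges[:, 1]]
    g = np.array([1.0, 1.0, 1.0, config.gamma])
    e_s = float(((diff * g) ** 2).sum())
    valid = landmarks.valid_mask
    k = landmarks.template_indices[valid]
    e_l = float(((deformed[k] - landmarks.points[valid]) ** 2).sum())
    return e_d + alpha * e_s + beta * e_l, e_d, e_s, e_l


def nicp_register(template: TriangleMesh, target: TriangleMesh,
                  template_landmarks: LandmarkSet,
                  target_landmarks: LandmarkSet,
                  config: NICPConfig | None = None) -> RegistrationResult:
    """Register the template onto a raw scan.

    ``template_landmarks`` must carry template vertex indices;
    ``target_landmarks`` carries the matching 3D locations on the scan
    (masked entries are ignored).  At least 3 mutually valid pairs are
    required for the initial similarity alignment.  Returns the deformed
    template on the template topology together with per-vertex surface
    distances and the hole/filled mask.
    """
    config = config or NICPConfig()
    if template_landmarks.template_indices is None:
        raise ValueError("template landmarks must carry template_indices")
    if list(template_landmarks.labels) != list(target_landmarks.labels):
        raise ValueError("template and target landmarks disagree on labels")
    mutual = template_landmarks.valid_mask & target_landmarks.valid_mask
    if mutual.sum() < 3:
        raise ValueError(f"need >= 3 mutually valid landmarks, "
                         f"have {int(mutual.sum())}")
    k_idx = template_landmarks.template_indices[mutual]
    ell = target_landmarks.points[mutual]

    # initial similarity alignment of the template into the scan frame
    init_tf = procrustes_align(template.points[k_idx], ell, allow_scale=True)
    v = init_tf.apply(template.points)
    n = len(v)
    if config.tps_initialization and mutual.sum() >= 5:
        try:
            from scipy.interpolate import RBFInterpolator
            tps = RBFInterpolator(v[k_idx], ell,
                                  kernel="thin_plate_spline", degree=1)
            v = tps(v)
        except np.linalg.LinAlgError:
            log.warning("degenerate landmark set; TPS initialization "
                        "skipped, similarity alignment only")

    max_dist = config.max_correspondence_dist
    if max_dist is None:
        scale = init_tf.scale
        max_dist = 5.0 * template.mean_edge_length() * scale
    cos_thresh = np.cos(np.deg2rad(config.normal_compatibility_deg))

    surf = SurfaceIndex(target)
    tgt_tris = target.triangles
    tgt_fnormals = np.cross(tgt_tris[:, 1] - tgt_tris[:, 0],
                            tgt_tris[:, 2] - tgt_tris[:, 0])
    tgt_fnormals /= np.maximum(
        np.linalg.norm(tgt_fnormals, axis=1, keepdims=True), 1e-300)

    KG = _edge_structure(template, config.gamma)
    K_s = (KG.T @ KG).tocsr()
    D = _data_matrix(v)
    DL = D[k_idx]
    DLtDL = (DL.T @ DL).tocsr()
    DLtL = DL.T @ ell

    X = np.zeros((4 * n, 3))
    X[0::4, 0] = X[1::4, 1] = X[2::4, 2] = 1.0  # identity stack, row-major
    deformed = v.copy()
    energy_pairs: list[tuple[float, float]] = []
    weights = np.ones(n)

    def quadratic_energy(Xm, w, corr, alpha, beta) -> float:
        r_d = D @ Xm - corr
        e_d = float((w[:, None] * r_d ** 2).sum())
        e_s = float(((KG @ Xm) ** 2).sum())
        r_l = DL @ Xm - ell
        return e_d + alpha * e_s + beta * float((r_l ** 2).sum())

    for level, (alpha, beta) in enumerate(zip(config.stiffness_schedule,
                                              config.landmark_schedule)):
        for _ in range(config.max_inner_iters):
            # (i) closest-point correspondences from current deformation
            corr, dists, tris = surf.closest_points(deformed)
            tm_normals = template.with_points(deformed).vertex_normals()
            compat = np.einsum("ij,ij->i", tm_normals,
                               tgt_fnormals[tris]) > cos_thresh
            weights = ((dists <= max_dist)
                       & ~surf.triangle_touches_boundary(tris)
                       & compat).astype(float)
            # (ii) exact sparse least-squares solve at fixed correspondences
            W = sp.diags(weights)
            N = (alpha * K_s + (D.T @ W @ D)).tocsc()
            rhs = D.T @ (weights[:, None] * corr)
            if beta > 0:
                N = N + beta * DLtDL
                rhs = rhs + beta * DLtL
            e_before = quadratic_energy(X, weights, corr, alpha, beta)
            try:
                lu = splu(N)
            except RuntimeError as e:
                ncomp, _ = connected_components(
                    sp.csr_matrix((np.ones(len(template.edges())),
                                   template.edges().T), shape=(n, n)),
                    directed=False)
                raise RuntimeError(
                    f"singular NICP system (template has {ncomp} connected "
                    f"components)") from e
            X_new = np.column_stack([lu.solve(rhs[:, c]) for c in range(3)])
            e_after = quadratic_energy(X_new, weights, corr, alpha, beta)
            energy_pairs.append((e_before, e_after))
            X = X_new
            new_deformed = np.asarray(D @ X)
            displacement = float(np.linalg.norm(
                new_deformed - deformed, axis=1).mean())
            deformed = new_deformed
            if displacement < config.inner_tolerance:
                break
        log.debug("stiffness level %d (alpha=%.3g): %d dropped vertices",
                  level, alpha, int((weights == 0).sum()))

    transforms = AffineStack(X.reshape(n, 4, 3).transpose(0, 2, 1))
    _, final_dists, _ = surf.closest_points(deformed)
    final_energy, _, _, _ = nicp_energy(
        transforms, template.with_points(v), target,
        LandmarkSet(labels=[l for l, m in zip(template_landmarks.labels,
                                              mutual) if m],
                    points=ell, template_indices=k_idx),
        config, config.stiffness_schedule[-1], config.landmark_schedule[-1],
        _surface=surf)
    result = RegistrationResult(
        deformed_template=template.with_points(deformed),
        transforms=transforms,
        per_vertex_distance=final_dists,
        filled_mask=weights == 0,
        final_energy=final_energy,
        inner_energy_pairs=energy_pairs,
        initial_alignment=init_tf)
    return result
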