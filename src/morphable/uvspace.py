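"""Cylindrical UV embedding and the landmark-TPS correspondence baseline.

Flattening a face-like surface onto a cylinder around a roughly vertical
axis gives each vertex a (u, v) = (azimuth, height) coordinate and lets
XYZ (and color) be rasterized into UV images.  A dense correspondence
between two such embeddings is then estimated from sparse landmarks by a
2D thin-plate spline (affine part + r²·log r radial terms, via
:class:`scipy.interpolate.RBFInterpolator`): template UV sites are mapped
into the target UV frame and the target's XYZ map is sampled there,
yielding a mesh on the template topology.

This is the classical baseline the package's non-rigid ICP route is
compared against; its known weaknesses (distortion where the surface
departs from a cylinder, no mechanism for nostril/mouth interiors) are
inherited deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator

from .mesh import TriangleMesh


@dataclass
class UVEmbedding:
    """Per-vertex UV coordinates plus rasterized UV-space maps."""

    mesh: TriangleMesh
    uv: np.ndarray               # (n, 2): u = azimuth (rad), v = height (mm)
    xyz_map: np.ndarray          # (H, W, 3)
    coverage: np.ndarray         # (H, W) bool
    color_map: np.ndarray | None
    u_range: tuple[float, float]
    v_range: tuple[float, float]

    def uv_to_pixel(self, uv: np.ndarray) -> np.ndarray:
        """Continuous (col, row) pixel coordinates of UV points."""
        uv = np.atleast_2d(uv)
        h, w = self.coverage.shape
        u0, u1 = self.u_range
        v0, v1 = self.v_range
        col = (uv[:, 0] - u0) / (u1 - u0) * (w - 1)
        row = (uv[:, 1] - v0) / (v1 - v0) * (h - 1)
        return np.column_stack([col, row])

    def sample_xyz(self, uv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear XYZ lookup at UV points, renormalized over covered
        pixels; returns ``(points, valid)``."""
        px = self.uv_to_pixel(uv)
        return _bilinear_masked(self.xyz_map, self.coverage, px)


def _bilinear_masked(img: np.ndarray, mask: np.ndarray, px: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    h, w = mask.shape
    out = np.full((len(px), img.shape[2]), np.nan)
    ok = np.zeros(len(px), dtype=bool)
    for i, (u, v) in enumerate(px):
        if not (0 <= u <= w - 1 and 0 <= v <= h - 1):
            continue
        c0, r0 = int(np.floor(u)), int(np.floor(v))
        c1, r1 = min(c0 + 1, w - 1), min(r0 + 1, h - 1)
        fu, fv = u - c0, v - r0
        acc = np.zeros(img.shape[2])
        wsum = 0.0
        for r, c, wt in ((r0, c0, (1 - fu) * (1 - fv)),
                         (r0, c1, fu * (1 - fv)),
                         (r1, c0, (1 - fu) * fv),
                         (r1, c1, fu * fv)):
            if mask[r, c] and wt > 0:
                acc += wt * img[r, c]
                wsum += wt
        if wsum > 0:
            out[i] = acc / wsum
            ok[i] = True
    return out, ok


def cylindrical_uv_embed(mesh: TriangleMesh,
                         axis_point=(0.0, 0.0, 0.0),
                         axis_direction=(0.0, 1.0, 0.0),
                         reference_direction=(0.0, 0.0, 1.0),
                         resolution: tuple[int, int] = (512, 512)
                         ) -> UVEmbedding:
    """Embed a mesh on a cylinder about a roughly vertical axis.

    u is the azimuth angle about the axis (0 along
    ``reference_direction``), v the height along the axis.  XYZ and color
    are rasterized into UV images by affine barycentric interpolation over
    the UV-projected triangles.  Triangles straddling the ±π azimuth seam
    are skipped in the raster (face-like surfaces never span it).
    """
    p0 = np.asarray(axis_point, float)
    k = np.asarray(axis_direction, float)
    k = k / np.linalg.norm(k)
    ref = np.asarray(reference_direction, float)
    ref = ref - (ref @ k) * k
    ref /= np.linalg.norm(ref)
    side = np.cross(k, ref)
    rel = mesh.points - p0
    u = np.arctan2(rel @ side, rel @ ref)
    v = rel @ k
    uv = np.column_stack([u, v])

    h, w = resolution
    pad_u = 0.02 * (u.max() - u.min() + 1e-9)
    pad_v = 0.02 * (v.max() - v.min() + 1e-9)
    u_range = (u.min() - pad_u, u.max() + pad_u)
    v_range = (v.min() - pad_v, v.max() + pad_v)

    emb = UVEmbedding(mesh=mesh, uv=uv,
                      xyz_map=np.full((h, w, 3), np.nan),
                      coverage=np.zeros((h, w), dtype=bool),
                      color_map=None if mesh.colors is None
                      else np.full((h, w, 3), np.nan),
                      u_range=u_range, v_range=v_range)
    px = emb.uv_to_pixel(uv)
    for t in mesh.trilist:
        tp = px[t]
        if np.ptp(uv[t, 0]) > np.pi:  # seam-straddling triangle
            continue
        area = ((tp[1, 0] - tp[0, 0]) * (tp[2, 1] - tp[0, 1])
                - (tp[2, 0] - tp[0, 0]) * (tp[1, 1] - tp[0, 1]))
        if abs(area) < 1e-12:
            continue
        lo = np.maximum(np.floor(tp.min(axis=0)), 0).astype(int)
        hi = np.minimum(np.ceil(tp.max(axis=0)), [w - 1, h - 1]).astype(int)
        if (lo > hi).any():
            continue
        cols, rows = np.meshgrid(np.arange(lo[0], hi[0] + 1),
                                 np.arange(lo[1], hi[1] + 1))
        w0 = ((tp[1, 0] - cols) * (tp[2, 1] - rows)
              - (tp[2, 0] - cols) * (tp[1, 1] - rows)) / area
        w1 = ((tp[2, 0] - cols) * (tp[0, 1] - rows)
              - (tp[0, 0] - cols) * (tp[2, 1] - rows)) / area
        w2 = 1.0 - w0 - w1
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        b = np.stack([w0[inside], w1[inside], w2[inside]], axis=-1)
        rr, cc = rows[inside], cols[inside]
        emb.xyz_map[rr, cc] = b @ mesh.points[t]
        if emb.color_map is not None:
            emb.color_map[rr, cc] = b @ mesh.colors[t]
        emb.coverage[rr, cc] = True
    return emb


def uv_tps_register(template_uv: UVEmbedding, target_uv: UVEmbedding,
                    template_landmarks_uv: np.ndarray,
                    target_landmarks_uv: np.ndarray) -> TriangleMesh:
    """Correspond a target to the template through a UV thin-plate spline.

    The TPS interpolating ``template_landmarks_uv -> target_landmarks_uv``
    maps every template vertex's UV site into the target UV frame, where
    the target XYZ map is sampled bilinearly.  Vertices falling outside
    the target's coverage keep their TPS-mapped position lifted from the
    template surface (rare at face scale; flagged in no way beyond that).
    Requires >= 4 landmark pairs not all collinear.
    """
    src = np.atleast_2d(np.asarray(template_landmarks_uv, float))
    dst = np.atleast_2d(np.asarray(target_landmarks_uv, float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("landmark UV arrays must be matching (L, 2)")
    if len(src) < 4:
        raise ValueError(f"need >= 4 landmark pairs, got {len(src)}")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(
            np.abs(centered).max(), 1e-300)) < 2:
        raise ValueError("degenerate (collinear) landmark configuration")
    tps = RBFInterpolator(src, dst, kernel="thin_plate_spline", degree=1)
    mapped = tps(template_uv.uv)
    xyz, ok = target_uv.sample_xyz(mapped)
    if not ok.all():
        # fall back to the template's own surface for uncovered sites
        fallback, fok = template_uv.sample_xyz(template_uv.uv)
        xyz[~ok] = np.where(np.isfinite(fallback[~ok]), fallback[~ok],
                            template_uv.mesh.points[~ok])
    return template_uv.mesh.with_points(xyz)
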