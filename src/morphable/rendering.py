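"""Virtual-camera rendering of meshes with per-pixel world coordinates.

Landmarking needs synthetic views of each scan in which every covered
pixel knows the exact 3D surface point it images.  :func:`render_view`
is a z-buffered perspective rasterizer with perspective-correct
barycentric interpolation of world XYZ and per-vertex color, so a pixel
whose ray meets a triangle at barycentric point b receives exactly the
b-weighted combination of that triangle's vertex attributes.  Colors are
rendered unlit — the XYZ shape image, the quantity the pipeline consumes,
is independent of any shading model.  Back faces are culled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriangleMesh

_BACKGROUND = 0.0
_NEAR = 1e-6


@dataclass
class VirtualCamera:
    """Perspective pinhole camera.

    ``rotation`` rows are the camera's right / up / forward axes in world
    coordinates; ``position`` is the optical centre.  A world point maps to
    camera frame as R @ (x − position), then to pixel coordinates

        u = cx + fx·x/z,   v = cy − fy·y/z

    (v grows downwards, so the world 'up' axis points up in the image).
    """

    position: np.ndarray        # (3,)
    rotation: np.ndarray        # (3, 3) rows right/up/forward
    focal: tuple[float, float]  # (fx, fy) pixels
    principal: tuple[float, float]  # (cx, cy) pixels
    image_shape: tuple[int, int]    # (height, width)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float).reshape(3)
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        if abs(abs(np.linalg.det(self.rotation)) - 1.0) > 1e-6:
            raise ValueError("camera rotation must be orthonormal")
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise ValueError("image size must be positive")

    def to_camera(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.position) @ self.rotation.T

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project world points; returns (L×2 [u, v] pixels, depths)."""
        pc = self.to_camera(points)
        z = pc[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = self.principal[0] + self.focal[0] * pc[:, 0] / z
            v = self.principal[1] - self.focal[1] * pc[:, 1] / z
        return np.column_stack([u, v]), z


def look_at_camera(position, target, image_shape=(512, 512),
                   up=(0.0, 1.0, 0.0), fov_deg: float = 30.0
                   ) -> VirtualCamera:
    """Camera at ``position`` looking at ``target`` with a given vertical
    field of view."""
    position = np.asarray(position, float)
    forward = np.asarray(target, float) - position
    forward = forward / np.linalg.norm(forward)
    right = np.cross(forward, np.asarray(up, float))
    nr = np.linalg.norm(right)
    if nr < 1e-12:
        raise ValueError("view direction parallel to the up axis")
    right /= nr
    cam_up = np.cross(right, forward)
    h, w = image_shape
    f = 0.5 * h / np.tan(np.deg2rad(fov_deg) / 2.0)
    return VirtualCamera(position=position,
                         rotation=np.stack([right, cam_up, forward]),
                         focal=(f, f),
                         principal=((w - 1) / 2.0, (h - 1) / 2.0),
                         image_shape=(h, w))


def default_camera_rig(mesh: TriangleMesh,
                       yaw_angles_deg=(0.0, -30.0, 30.0, -60.0, 60.0),
                       image_shape=(512, 512),
                       distance_factor: float = 4.0,
                       forward_axis=(0.0, 0.0, 1.0)) -> list[VirtualCamera]:
    """Yaw arc of cameras around the mesh's vertical axis.

    Cameras sit at ``distance_factor`` × bounding-sphere radius from the
    centroid, at the given yaw angles about the world y axis relative to
    ``forward_axis`` (the direction the anatomy faces).
    """
    center = mesh.points.mean(axis=0)
    radius = float(np.linalg.norm(mesh.points - center, axis=1).max())
    dist = distance_factor * radius
    fwd = np.asarray(forward_axis, float)
    fwd = fwd / np.linalg.norm(fwd)
    fov = np.rad2deg(2.0 * np.arctan(1.3 * radius / dist))
    cams = []
    for yaw in yaw_angles_deg:
        a = np.deg2rad(yaw)
        c, s = np.cos(a), np.sin(a)
        Ry = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
        cams.append(look_at_camera(center + dist * (Ry @ fwd), center,
                                   image_shape=image_shape, fov_deg=fov))
    return cams


@dataclass
class RenderedView:
    """Raster output of one camera: texture + per-pixel world XYZ."""

    texture_image: np.ndarray   # (H, W, 3) in [0, 1]
    shape_image: np.ndarray     # (H, W, 3) world mm; NaN off-surface
    coverage_mask: np.ndarray   # (H, W) bool
    camera: VirtualCamera
    depth: np.ndarray | None = None  # (H, W) camera-frame z

    @property
    def is_empty(self) -> bool:
        return not bool(self.coverage_mask.any())


def render_view(mesh: TriangleMesh, camera: VirtualCamera,
                backface_cull: bool = True) -> RenderedView:
    """Rasterize one view with a z-buffer.

    Zero coverage (camera looking away, degenerate placement) is not an
    error; the view simply comes back empty.
    """
    h, w = camera.image_shape
    colors = (mesh.colors if mesh.colors is not None
              else np.full((mesh.n_points, 3), 0.6))
    uv, z = camera.project(mesh.points)
    zbuf = np.full((h, w), np.inf)
    shape_img = np.full((h, w, 3), np.nan)
    tex_img = np.full((h, w, 3), _BACKGROUND)

    tri = mesh.trilist
    tz = z[tri]
    visible = (tz > _NEAR).all(axis=1)
    if backface_cull:
        tris3d = mesh.triangles
        n = np.cross(tris3d[:, 1] - tris3d[:, 0], tris3d[:, 2] - tris3d[:, 0])
        view = tris3d.mean(axis=1) - camera.position
        visible &= np.einsum("ij,ij->i", n, view) < 0
    vt = tri[visible]
    if len(vt):
        p = uv[vt]                                   # (T, 3, 2)
        area = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
        ok = np.abs(area) > 1e-12
        vt, p = vt[ok], p[ok]
        lo = np.clip(np.floor(p.min(axis=1)), 0, [w - 1, h - 1]).astype(int)
        hi = np.clip(np.ceil(p.max(axis=1)), 0, [w - 1, h - 1]).astype(int)
        nx, ny = hi[:, 0] - lo[:, 0] + 1, hi[:, 1] - lo[:, 1] + 1
        counts = nx * ny
        keep = counts > 0
        vt, p, lo, nx, ny, counts = (vt[keep], p[keep], lo[keep], nx[keep],
                                     ny[keep], counts[keep])
        # flatten every triangle's bounding-box pixels into one array
        tidx = np.repeat(np.arange(len(vt)), counts)
        local = np.arange(counts.sum()) - np.repeat(
            np.concatenate([[0], np.cumsum(counts)[:-1]]), counts)
        px = lo[tidx, 0] + local % nx[tidx]
        py = lo[tidx, 1] + local // nx[tidx]
        a, b3, c = p[tidx, 0], p[tidx, 1], p[tidx, 2]
        w0 = (b3[:, 0] - px) * (c[:, 1] - py) - (c[:, 0] - px) * (b3[:, 1] - py)
        w1 = (c[:, 0] - px) * (a[:, 1] - py) - (a[:, 0] - px) * (c[:, 1] - py)
        w2 = (a[:, 0] - px) * (b3[:, 1] - py) - (b3[:, 0] - px) * (a[:, 1] - py)
        denom = w0 + w1 + w2
        sgn = np.sign(denom)
        inside = ((sgn * w0 >= 0) & (sgn * w1 >= 0) & (sgn * w2 >= 0)
                  & (np.abs(denom) > 1e-12))
        tidx, px, py = tidx[inside], px[inside], py[inside]
        bary = (np.stack([w0[inside], w1[inside], w2[inside]], axis=-1)
                / denom[inside, None])               # screen-space
        invz = bary / z[vt[tidx]]                    # perspective correction
        zp = 1.0 / invz.sum(axis=1)
        bc = invz * zp[:, None]                      # surface barycentric
        # z-buffer: per-pixel minimum over all candidate fragments
        pid = py * w + px
        zflat = np.full(h * w, np.inf)
        np.minimum.at(zflat, pid, zp)
        win = zp <= zflat[pid]
        pid, zp, bc, tidx = pid[win], zp[win], bc[win], tidx[win]
        zbuf.reshape(-1)[pid] = zp
        shape_img.reshape(-1, 3)[pid] = np.einsum(
            "fk,fkc->fc", bc, mesh.points[vt[tidx]])
        tex_img.reshape(-1, 3)[pid] = np.einsum(
            "fk,fkc->fc", bc, colors[vt[tidx]])
    coverage = np.isfinite(zbuf)
    return RenderedView(texture_image=tex_img, shape_image=shape_img,
                        coverage_mask=coverage, camera=camera, depth=zbuf)


def render_views(mesh: TriangleMesh, cameras: list[VirtualCamera],
                 backface_cull: bool = True) -> list[RenderedView]:
    """One :class:`RenderedView` per camera (deterministic)."""
    return [render_view(mesh, c, backface_cull=backface_cull)
            for c in cameras]
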