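"""Mesh and landmark file I/O.

Supported mesh formats are Wavefront OBJ (``v``/``f`` records, with the
common per-vertex color extension ``v x y z r g b``) and PLY (ascii or
binary little-endian, via :mod:`trimesh`).  Indices are converted to the
package's 0-based convention at this boundary.  Coordinates are held at 64
bits in memory; PLY files are written with 32-bit float vertex properties,
the dialect virtually all consumers expect, so a PLY round trip preserves
coordinates to float32 resolution and colors to 1/255 per channel.

Landmark files are a small JSON schema::

    {"version": 1, "labels": [...], "points": [[x, y, z], ...],
     "valid": [...]}

Points whose ``valid`` entry is false may carry non-finite coordinates.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import numpy as np
import trimesh

from .mesh import LandmarkSet, MeshValidationError, TriangleMesh

log = logging.getLogger(__name__)


class MeshParseError(ValueError):
    """A mesh file could not be parsed; the message names the location."""


class LandmarkSchemaError(ValueError):
    """A landmark JSON file does not follow the expected schema."""


def _infer_format(path: os.PathLike | str, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt not in ("obj", "ply"):
        raise ValueError(f"unsupported mesh format {fmt!r} (obj or ply)")
    return fmt


def _read_obj(path: Path) -> TriangleMesh:
    points: list[list[float]] = []
    colors: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if tok[0] == "v":
                try:
                    vals = [float(t) for t in tok[1:]]
                except ValueError:
                    raise MeshParseError(
                        f"{path}:{lineno}: bad vertex record {line!r}")
                if len(vals) not in (3, 6):
                    raise MeshParseError(
                        f"{path}:{lineno}: vertex needs 3 or 6 floats, "
                        f"got {len(vals)}")
                points.append(vals[:3])
                if len(vals) == 6:
                    colors.append(vals[3:])
            elif tok[0] == "f":
                if len(tok) != 4:
                    raise MeshParseError(
                        f"{path}:{lineno}: only triangular faces supported, "
                        f"got {len(tok) - 1} corners")
                idx = []
                for t in tok[1:]:
                    head = t.split("/")[0]
                    try:
                        i = int(head)
                    except ValueError:
                        raise MeshParseError(
                            f"{path}:{lineno}: bad face index {t!r}")
                    # OBJ is 1-based; negative indices count from the end
                    idx.append(i - 1 if i > 0 else len(points) + i)
                faces.append(idx)
            # other records (vn, vt, usemtl, ...) are ignored
    if colors and len(colors) != len(points):
        raise MeshParseError(
            f"{path}: {len(colors)} colored of {len(points)} vertices; "
            "per-vertex color must cover every vertex")
    try:
        return TriangleMesh(
            points=np.asarray(points, dtype=np.float64).reshape(-1, 3),
            trilist=np.asarray(faces, dtype=np.int64).reshape(-1, 3),
            colors=np.asarray(colors, dtype=np.float64) if colors else None)
    except MeshValidationError as e:
        raise MeshValidationError(f"{path}: {e}") from e


def _read_ply(path: Path) -> TriangleMesh:
    try:
        tm = trimesh.load(str(path), file_type="ply", process=False)
    except Exception as e:  # trimesh raises a zoo of types on bad input
        raise MeshParseError(f"{path}: PLY parse failed: {e}") from e
    if not isinstance(tm, trimesh.Trimesh):
        raise MeshParseError(f"{path}: PLY does not contain a triangle mesh")
    colors = None
    vc = getattr(tm.visual, "vertex_colors", None)
    if (vc is not None and len(vc) == len(tm.vertices)
            and tm.visual.kind == "vertex"):
        colors = np.asarray(vc[:, :3], dtype=np.float64) / 255.0
    try:
        return TriangleMesh(points=np.asarray(tm.vertices, dtype=np.float64),
                            trilist=np.asarray(tm.faces, dtype=np.int64),
                            colors=colors)
    except MeshValidationError as e:
        raise MeshValidationError(f"{path}: {e}") from e


def read_mesh(path: os.PathLike | str, format: str | None = None
              ) -> TriangleMesh:
    """Read an OBJ or PLY file into a validated :class:`TriangleMesh`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    return _read_obj(path) if fmt == "obj" else _read_ply(path)


def write_mesh(mesh: TriangleMesh, path: os.PathLike | str,
               format: str | None = None, obj_colors: bool = True) -> None:
    """Write a mesh as OBJ or PLY.

    OBJ colors use the widespread ``v x y z r g b`` extension; pass
    ``obj_colors=False`` to target strict OBJ readers, in which case the
    colors are dropped with a logged warning and the geometry written
    unchanged.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "obj":
        write_colors = mesh.colors is not None
        if write_colors and not obj_colors:
            log.warning("%s: strict OBJ dialect has no per-vertex color; "
                        "colors dropped, geometry written unchanged", path)
            write_colors = False
        with open(path, "w") as fh:
            for i, p in enumerate(mesh.points):
                if write_colors:
                    c = mesh.colors[i]
                    fh.write(f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g} "
                             f"{c[0]:.9g} {c[1]:.9g} {c[2]:.9g}\n")
                else:
                    fh.write(f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            for t in mesh.trilist:
                fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
    else:
        tm = trimesh.Trimesh(vertices=mesh.points, faces=mesh.trilist,
                             process=False)
        if mesh.colors is not None:
            rgba = np.empty((mesh.n_points, 4), dtype=np.uint8)
            rgba[:, :3] = np.round(mesh.colors * 255).astype(np.uint8)
            rgba[:, 3] = 255
            tm.visual.vertex_colors = rgba
        with open(path, "wb") as fh:
            fh.write(trimesh.exchange.ply.export_ply(
                tm, encoding="binary_little_endian"))


def read_landmarks(path: os.PathLike | str) -> LandmarkSet:
    """Read a landmark JSON file."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise LandmarkSchemaError(f"{path}: not valid JSON: {e}") from e
    for key in ("labels", "points"):
        if key not in doc:
            raise LandmarkSchemaError(f"{path}: missing required key {key!r}")
    labels = doc["labels"]
    points = np.asarray(doc["points"], dtype=np.float64)
    if points.ndim != 2 or points.shape != (len(labels), 3):
        raise LandmarkSchemaError(
            f"{path}: points must be {len(labels)}x3, got {points.shape}")
    valid = doc.get("valid")
    tidx = doc.get("template_indices")
    try:
        return LandmarkSet(
            labels=labels, points=points,
            valid_mask=None if valid is None else np.asarray(valid, bool),
            template_indices=None if tidx is None
            else np.asarray(tidx, np.int64))
    except MeshValidationError as e:
        raise LandmarkSchemaError(f"{path}: {e}") from e


def write_landmarks(lms: LandmarkSet, path: os.PathLike | str) -> None:
    """Write a landmark set as JSON (exact float round trip via repr)."""
    doc = {"version": 1,
           "labels": list(lms.labels),
           "points": [[float(x) for x in p] for p in lms.points],
           "valid": [bool(v) for v in lms.valid_mask]}
    if lms.template_indices is not None:
        doc["template_indices"] = [int(i) for i in lms.template_indices]
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")
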