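"""Core mesh and landmark containers.

All geometry is held in millimetres, all indices 0-based.  A
:class:`TriangleMesh` is the single mesh container used throughout the
package: raw scans, templates and deformed templates are all instances of
it.  A :class:`LandmarkSet` carries a sparse, named annotation of a mesh
and may additionally pin each landmark to a template vertex index, which is
how the landmark term of the non-rigid registration knows which template
vertices it constrains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


class MeshValidationError(ValueError):
    """A mesh or landmark container violates a structural invariant."""


@dataclass
class TriangleMesh:
    """Triangle mesh with optional per-vertex color.

    Parameters
    ----------
    points : (n, 3) float array
        Vertex coordinates in millimetres.
    trilist : (m, 3) int array
        0-based vertex index triplets.
    colors : (n, 3) float array, optional
        Per-vertex RGB, each channel in [0, 1].
    """

    points: np.ndarray
    trilist: np.ndarray
    colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        self.trilist = np.ascontiguousarray(self.trilist, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise MeshValidationError(
                f"points must be (n, 3), got {self.points.shape}")
        if self.trilist.size == 0:
            self.trilist = self.trilist.reshape(0, 3)
        if self.trilist.ndim != 2 or self.trilist.shape[1] != 3:
            raise MeshValidationError(
                f"trilist must be (m, 3), got {self.trilist.shape}")
        n = len(self.points)
        if self.trilist.size and (
                self.trilist.min() < 0 or self.trilist.max() >= n):
            bad = self.trilist[(self.trilist < 0).any(axis=1)
                               | (self.trilist >= n).any(axis=1)][0]
            raise MeshValidationError(
                f"trilist references vertex outside [0, {n}): {bad.tolist()}")
        degen = ((self.trilist[:, 0] == self.trilist[:, 1])
                 | (self.trilist[:, 1] == self.trilist[:, 2])
                 | (self.trilist[:, 0] == self.trilist[:, 2]))
        if degen.any():
            raise MeshValidationError(
                f"triangle {int(np.flatnonzero(degen)[0])} repeats a vertex")
        if self.colors is not None:
            self.colors = np.ascontiguousarray(self.colors, dtype=np.float64)
            if self.colors.shape != (n, 3):
                raise MeshValidationError(
                    f"colors must be ({n}, 3), got {self.colors.shape}")
            if self.colors.min() < 0 or self.colors.max() > 1:
                raise MeshValidationError("color channels must lie in [0, 1]")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_tris(self) -> int:
        return len(self.trilist)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle vertex coordinates."""
        return self.points[self.trilist]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (e, 2) sorted index array."""
        e = np.vstack([self.trilist[:, [0, 1]],
                       self.trilist[:, [1, 2]],
                       self.trilist[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def mean_edge_length(self) -> float:
        e = self.edges()
        return float(np.linalg.norm(
            self.points[e[:, 0]] - self.points[e[:, 1]], axis=1).mean())

    def boundary_vertices(self) -> np.ndarray:
        """Indices of vertices on a boundary (edge used by one triangle)."""
        e = np.vstack([self.trilist[:, [0, 1]],
                       self.trilist[:, [1, 2]],
                       self.trilist[:, [2, 0]]])
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return np.unique(uniq[counts == 1])

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex unit normals."""
        tris = self.triangles
        fn = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
        vn = np.zeros_like(self.points)
        for k in range(3):
            np.add.at(vn, self.trilist[:, k], fn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return vn / norms

    def with_points(self, points: np.ndarray) -> "TriangleMesh":
        """Same topology and colors with replaced vertex positions."""
        return TriangleMesh(points=np.asarray(points, dtype=np.float64),
                            trilist=self.trilist.copy(),
                            colors=None if self.colors is None
                            else self.colors.copy())

    def as_vector(self) -> np.ndarray:
        """Flatten points to a length-3n vector (x0, y0, z0, x1, ...)."""
        return self.points.reshape(-1).copy()

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.points.copy(), self.trilist.copy(),
                            None if self.colors is None else self.colors.copy())


@dataclass
class LandmarkSet:
    """Named sparse 3D annotation, optionally pinned to template vertices."""

    labels: list[str]
    points: np.ndarray
    template_indices: np.ndarray | None = None
    valid_mask: np.ndarray | None = None
    confidences: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise MeshValidationError("landmark labels must be unique")
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        L = len(self.labels)
        if len(self.points) != L:
            raise MeshValidationError(
                f"{L} labels but {len(self.points)} points")
        if self.valid_mask is None:
            self.valid_mask = np.ones(L, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (L,):
                raise MeshValidationError("valid_mask length mismatch")
        if not np.isfinite(self.points[self.valid_mask]).all():
            raise MeshValidationError("valid landmark has non-finite point")
        if self.template_indices is not None:
            self.template_indices = np.asarray(self.template_indices,
                                               dtype=np.int64)
            if self.template_indices.shape != (L,):
                raise MeshValidationError("template_indices length mismatch")
        if self.confidences is not None:
            self.confidences = np.asarray(self.confidences, dtype=np.float64)
            if self.confidences.shape != (L,):
                raise MeshValidationError("confidences length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.points[self.index(label)]

    def valid_subset(self) -> "LandmarkSet":
        m = self.valid_mask
        return LandmarkSet(
            labels=[l for l, v in zip(self.labels, m) if v],
            points=self.points[m],
            template_indices=None if self.template_indices is None
            else self.template_indices[m],
            confidences=None if self.confidences is None
            else self.confidences[m])

    def copy(self) -> "LandmarkSet":
        return replace(
            self, labels=list(self.labels), points=self.points.copy(),
            template_indices=None if self.template_indices is None
            else self.template_indices.copy(),
            valid_mask=self.valid_mask.copy(),
            confidences=None if self.confidences is None
            else self.confidences.copy())


@dataclass(frozen=True)
class DemographicRecord:
    """Per-subject metadata driving bespoke model selection."""

    subject_id: str
    age: float
    gender: str
    ethnicity: str

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")
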