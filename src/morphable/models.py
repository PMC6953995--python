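"""Linear statistical models of shape and texture.

A :class:`LinearModel` is the classic morphable-model parameterization: a
mean vector X̄, an orthonormal basis U whose columns are principal
directions, and the per-component variances λ_i.  A novel instance is
X* = X̄ + U·α; any vector projects onto the subspace through
α = Uᵀ(X − X̄), P(X) = X̄ + U·α.  Random instances draw each coefficient
independently from N(0, λ_i).

PCA is computed through a thin SVD of the centered data matrix — in the
k ≪ 3n regime typical of mesh collections the 3n×3n covariance is never
materialized.  Eigenvector signs are fixed by making each column's
largest-magnitude entry positive so rebuilds are bit-reproducible.

:class:`BespokeModelSet` routes a demographic record to the model trained
on its subgroup (age band × ethnicity by default), falling back to the
global model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import h5py
import numpy as np

from .mesh import DemographicRecord, TriangleMesh


@dataclass
class LinearModel:
    """Mean + orthonormal basis + eigenvalues (shape or texture)."""

    mean: np.ndarray          # (3n,)
    basis: np.ndarray         # (3n, d), orthonormal columns
    eigenvalues: np.ndarray   # (d,), non-increasing, >= 0
    trilist: np.ndarray       # shared topology
    kind: str = "shape"       # {"shape", "texture"}
    total_variance: float | None = None  # variance incl. discarded modes
    n_training: int | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).reshape(-1)
        self.basis = np.asarray(self.basis, dtype=np.float64)
        self.eigenvalues = np.asarray(self.eigenvalues,
                                      dtype=np.float64).reshape(-1)
        if self.basis.ndim != 2 or self.basis.shape[0] != self.mean.size:
            raise ValueError("basis must be (3n, d)")
        if self.basis.shape[1] != self.eigenvalues.size:
            raise ValueError("one eigenvalue per basis column required")
        if np.any(np.diff(self.eigenvalues) > 1e-10 * max(
                self.eigenvalues[0] if self.eigenvalues.size else 1.0, 1e-300)):
            raise ValueError("eigenvalues must be non-increasing")
        if self.eigenvalues.size and self.eigenvalues[-1] < -1e-12:
            raise ValueError("eigenvalues must be non-negative")
        if self.kind not in ("shape", "texture"):
            raise ValueError(f"kind must be shape or texture, got {self.kind}")
        if self.total_variance is None:
            self.total_variance = float(self.eigenvalues.sum())

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.mean.size // 3

    def truncated(self, n_components: int) -> "LinearModel":
        """Model retaining only the leading components (nested subspace)."""
        c = int(n_components)
        if not 0 <= c <= self.n_components:
            raise ValueError(f"n_components must be in [0, "
                             f"{self.n_components}], got {c}")
        return LinearModel(self.mean, self.basis[:, :c],
                           self.eigenvalues[:c], self.trilist, self.kind,
                           total_variance=self.total_variance,
                           n_training=self.n_training)

    def components_for_variance(self, fraction: float) -> int:
        """Smallest component count explaining >= fraction of the model's
        total variance."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        cum = np.cumsum(self.eigenvalues)
        total = self.total_variance or cum[-1]
        hit = np.flatnonzero(cum >= fraction * total - 1e-12)
        return int(hit[0]) + 1 if hit.size else self.n_components

    def mean_mesh(self) -> TriangleMesh:
        return TriangleMesh(self.mean.reshape(-1, 3), self.trilist)


def build_pca(samples: np.ndarray | Sequence[np.ndarray],
              trilist: np.ndarray,
              variance_to_retain: float | None = None,
              n_components: int | None = None,
              kind: str = "shape") -> LinearModel:
    """PCA model from k sample vectors of length 3n.

    Exactly one of ``variance_to_retain`` (fraction in (0, 1]) or
    ``n_components`` may be given; with neither, all min(k−1, 3n)
    components are kept.  Eigenvalues are the sample variances along each
    principal direction (1/(k−1) normalization).
    """
    X = np.asarray([np.asarray(s, float).reshape(-1) for s in samples])
    k = len(X)
    if k < 2:
        raise ValueError(f"PCA needs at least 2 samples, got {k}")
    if variance_to_retain is not None and n_components is not None:
        raise ValueError("give variance_to_retain or n_components, not both")
    mean = X.mean(axis=0)
    Xc = X - mean
    # thin SVD of the k x 3n centered data matrix
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s ** 2 / (k - 1)
    # drop numerically-null modes (rank k-1 after centering)
    floor = max(eigvals[0], 1e-300) * 1e-14
    keep = eigvals > floor
    eigvals, basis = eigvals[keep], Vt[keep].T
    total_variance = float(eigvals.sum())
    if variance_to_retain is not None:
        cum = np.cumsum(eigvals)
        hit = np.flatnonzero(cum >= variance_to_retain * total_variance
                             - 1e-12)
        d = int(hit[0]) + 1 if hit.size else len(eigvals)
    elif n_components is not None:
        d = min(int(n_components), len(eigvals))
    else:
        d = len(eigvals)
    basis, eigvals = basis[:, :d], eigvals[:d]
    # deterministic sign: largest-|.| entry of each column positive
    flip = np.sign(basis[np.abs(basis).argmax(axis=0),
                         np.arange(basis.shape[1])])
    flip[flip == 0] = 1.0
    basis = basis * flip
    return LinearModel(mean=mean, basis=basis, eigenvalues=eigvals,
                       trilist=np.asarray(trilist, np.int64), kind=kind,
                       total_variance=total_variance, n_training=k)


def instance(model: LinearModel, coeffs: np.ndarray,
             as_mesh: bool | None = None) -> TriangleMesh | np.ndarray:
    """Synthesize X* = X̄ + U·α.  Short coefficient vectors are zero-padded;
    longer than d is an error."""
    a = np.asarray(coeffs, dtype=np.float64).reshape(-1)
    if a.size > model.n_components:
        raise ValueError(f"{a.size} coefficients for a "
                         f"{model.n_components}-component model")
    vec = model.mean + model.basis[:, :a.size] @ a
    if as_mesh is None:
        as_mesh = model.kind == "shape"
    if as_mesh:
        return TriangleMesh(vec.reshape(-1, 3), model.trilist)
    return vec


def project(model: LinearModel, X: np.ndarray,
            n_components: int | None = None
            ) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and subspace projection of a vector.

    α = Uᵀ(X − X̄) and P(X) = X̄ + U·α — the least-squares closest point
    of the model subspace, by orthonormality of U.  Returns ``(α, P(X))``.
    """
    x = np.asarray(X, dtype=np.float64).reshape(-1)
    if x.size != model.mean.size:
        raise ValueError(f"vector length {x.size} != model length "
                         f"{model.mean.size}")
    U = model.basis if n_components is None else model.basis[:, :n_components]
    alpha = U.T @ (x - model.mean)
    return alpha, model.mean + U @ alpha


def sample_random(model: LinearModel, rng: np.random.Generator | int,
                  n_components: int | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Draw α_i ~ N(0, λ_i) independently; returns ``(α, instance vector)``.

    Deterministic for a fixed seed / generator state.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    d = model.n_components if n_components is None else int(n_components)
    lam = model.eigenvalues[:d]
    alpha = rng.standard_normal(d) * np.sqrt(np.maximum(lam, 0.0))
    return alpha, model.mean + model.basis[:, :d] @ alpha


def transfer_color(source_mesh: TriangleMesh, target_points: np.ndarray,
                   tri_indices: np.ndarray | None = None,
                   bary_coords: np.ndarray | None = None) -> np.ndarray:
    """Barycentric per-vertex color pickup at points on the source surface.

    If triangle indices / barycentric coordinates are not supplied the
    points are located by an exact closest-point query first.
    """
    if source_mesh.colors is None:
        raise ValueError("source mesh has no colors")
    pts = np.atleast_2d(np.asarray(target_points, float))
    if tri_indices is None or bary_coords is None:
        from .surface import SurfaceIndex
        from trimesh.triangles import points_to_barycentric
        idx = SurfaceIndex(source_mesh)
        surf_pts, _, tri_indices = idx.closest_points(pts)
        bary_coords = points_to_barycentric(
            source_mesh.triangles[tri_indices], surf_pts)
    tri_colors = source_mesh.colors[source_mesh.trilist[tri_indices]]
    out = np.einsum("pk,pkc->pc", np.asarray(bary_coords, float), tri_colors)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# demographically bespoke model collections

Predicate = Callable[[DemographicRecord], bool]

#: Age bin edges shared by bespoke grouping and the age-classification demo.
#: Bins are half-open: [0, 7), [7, 18), [18, 50), [50, inf).
AGE_BIN_EDGES = (7.0, 18.0, 50.0)
AGE_BIN_LABELS = ("under-7", "7-to-18", "18-to-50", "over-50")


def age_bin(age: float) -> str:
    """Half-open age band label for an age in years."""
    for edge, label in zip(AGE_BIN_EDGES, AGE_BIN_LABELS):
        if age < edge:
            return label
    return AGE_BIN_LABELS[-1]


@dataclass
class BespokeModelSet:
    """Ordered (predicate -> model key) routing with a global fallback."""

    rules: list[tuple[Predicate, str]]
    models: dict[str, LinearModel]
    fallback_key: str = "global"

    def __post_init__(self) -> None:
        if self.fallback_key not in self.models:
            raise ValueError(f"fallback model {self.fallback_key!r} missing")
        for _, key in self.rules:
            if key not in self.models:
                raise ValueError(f"rule references unknown model {key!r}")

    def select(self, record: DemographicRecord) -> LinearModel:
        return self.models[self.select_key(record)]

    def select_key(self, record: DemographicRecord) -> str:
        for pred, key in self.rules:
            if pred(record):
                return key
        return self.fallback_key


def default_bespoke_rules(
        binned_ethnicities: Sequence[str] = ("White",),
        plain_ethnicities: Sequence[str] = ("Black", "Chinese"),
) -> list[tuple[Predicate, str]]:
    """Six-group demographic routing: one model per listed plain ethnicity
    plus one per age band of each age-binned ethnicity."""
    rules: list[tuple[Predicate, str]] = []
    for eth in plain_ethnicities:
        rules.append((lambda r, e=eth: r.ethnicity == e, eth))
    for eth in binned_ethnicities:
        for label in AGE_BIN_LABELS:
            rules.append(
                (lambda r, e=eth, b=label:
                 r.ethnicity == e and age_bin(r.age) == b,
                 f"{eth}-{label}"))
    return rules


def select_bespoke(model_set: BespokeModelSet,
                   record: DemographicRecord) -> LinearModel:
    """First matching rule's model; the global fallback otherwise."""
    return model_set.select(record)


# ---------------------------------------------------------------------------
# persistence

def save_model(model: LinearModel, path, key: str | None = None,
               mode: str = "w") -> None:
    """Persist a model to an HDF5 archive (bit-exact round trip).

    Layout: ``/mean``, ``/basis``, ``/eigenvalues``, ``/trilist`` datasets
    and a ``/meta`` group with kind / training count attributes.  Pass
    ``key`` to nest several models (e.g. bespoke groups) in one file.
    """
    with h5py.File(path, mode) as f:
        g = f.create_group(key) if key else f
        # track_times=False keeps archives byte-identical across reruns
        g.create_dataset("mean", data=model.mean, track_times=False)
        g.create_dataset("basis", data=model.basis, track_times=False)
        g.create_dataset("eigenvalues", data=model.eigenvalues,
                         track_times=False)
        g.create_dataset("trilist", data=model.trilist, track_times=False)
        meta = g.create_group("meta")
        meta.attrs["kind"] = model.kind
        meta.attrs["total_variance"] = float(model.total_variance)
        if model.n_training is not None:
            meta.attrs["n_training"] = int(model.n_training)


def load_model(path, key: str | None = None) -> LinearModel:
    with h5py.File(path, "r") as f:
        g = f[key] if key else f
        meta = g["meta"].attrs
        return LinearModel(
            mean=g["mean"][:], basis=g["basis"][:],
            eigenvalues=g["eigenvalues"][:], trilist=g["trilist"][:],
            kind=str(meta["kind"]),
            total_variance=float(meta["total_variance"]),
            n_training=int(meta["n_training"])
            if "n_training" in meta else None)
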