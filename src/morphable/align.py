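"""Similarity alignment: pairwise Procrustes and its generalized form.

Pairwise alignment follows the closed-form least-squares solution for a
similarity transform (rotation restricted to det = +1).  Generalized
Procrustes analysis (GPA) iteratively aligns a corresponded collection to
its evolving mean.  The mean is renormalized each iteration to the average
centroid size of the input shapes, so the aligned collection keeps the
data's millimetre scale while similarity effects (pose, scale) are removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriangleMesh


@dataclass(frozen=True)
class SimilarityTransform:
    """x -> scale * rotation @ x + translation."""

    scale: float
    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation.T + self.translation

    def compose(self, inner: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``inner`` then ``self``."""
        return SimilarityTransform(
            scale=self.scale * inner.scale,
            rotation=self.rotation @ inner.rotation,
            translation=self.scale * self.rotation @ inner.translation
            + self.translation)

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        return SimilarityTransform(
            scale=1.0 / self.scale, rotation=Rinv,
            translation=-Rinv @ self.translation / self.scale)


def centroid_size(points: np.ndarray) -> float:
    """Root-sum-of-squares distance of the points from their centroid."""
    c = points.mean(axis=0)
    return float(np.sqrt(((points - c) ** 2).sum()))


def procrustes_align(source_points: np.ndarray, target_points: np.ndarray,
                     allow_scale: bool = True) -> SimilarityTransform:
    """Least-squares similarity transform mapping source onto target.

    Closed-form solution via the SVD of the cross-covariance, with the
    reflection corrected to a proper rotation.  Requires >= 3 points in a
    configuration of rank >= 2.
    """
    src = np.asarray(source_points, dtype=np.float64)
    tgt = np.asarray(target_points, dtype=np.float64)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError(f"point sets must both be (k, 3); got {src.shape} "
                         f"and {tgt.shape}")
    if len(src) < 3:
        raise ValueError("need at least 3 point pairs")
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    sc, tc = src - mu_s, tgt - mu_t
    cov = tc.T @ sc / len(src)
    U, D, Vt = np.linalg.svd(cov)
    if np.linalg.matrix_rank(cov, tol=1e-10 * max(D[0], 1e-300)) < 2:
        raise ValueError("degenerate (rank < 2) point configuration")
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    if allow_scale:
        var_s = (sc ** 2).sum() / len(src)
        s = float((D * np.diag(S)).sum() / var_s)
    else:
        s = 1.0
    t = mu_t - s * R @ mu_s
    return SimilarityTransform(scale=s, rotation=R, translation=t)


def generalized_procrustes(
        meshes: list[TriangleMesh], allow_scale: bool = True,
        tol: float = 1e-7, max_iters: int = 100,
) -> tuple[list[TriangleMesh], TriangleMesh]:
    """Generalized Procrustes analysis of corresponded meshes.

    Returns ``(aligned meshes, mean mesh)``.  All meshes must share a
    topology.  Iterates align-to-mean until the relative change of the
    mean falls below ``tol``.  The mean's centroid sits at the origin and
    its centroid size equals the average centroid size of the inputs.
    """
    if not meshes:
        raise ValueError("empty mesh collection")
    trilist = meshes[0].trilist
    for m in meshes[1:]:
        if not np.array_equal(m.trilist, trilist):
            raise ValueError("meshes are not in correspondence "
                             "(topologies differ)")
    target_size = float(np.mean([centroid_size(m.points) for m in meshes]))
    pts = [m.points.copy() for m in meshes]
    if len(pts) == 1:
        mean = pts[0] - pts[0].mean(axis=0)
        mean *= target_size / centroid_size(mean)
        return ([meshes[0].with_points(mean.copy())],
                meshes[0].with_points(mean))

    def normalize(mean: np.ndarray) -> np.ndarray:
        mean = mean - mean.mean(axis=0)
        return mean * (target_size / centroid_size(mean))

    mean = normalize(pts[0])
    for _ in range(max_iters):
        for i in range(len(pts)):
            tf = procrustes_align(pts[i], mean, allow_scale=allow_scale)
            pts[i] = tf.apply(pts[i])
        new_mean = normalize(np.mean(pts, axis=0))
        change = np.linalg.norm(new_mean - mean) / max(
            np.linalg.norm(mean), 1e-300)
        mean = new_mean
        if change < tol:
            break
    aligned = [m.with_points(p) for m, p in zip(meshes, pts)]
    return aligned, meshes[0].with_points(mean)
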