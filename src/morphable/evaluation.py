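"""Intrinsic and fitting evaluation of linear shape models.

The standard shape-model battery:

* **compactness** — cumulative percentage of training variance explained
  as components are added;
* **generalization** — mean per-vertex distance between held-out shapes
  and their subspace projections, as a function of retained components;
* **specificity** — realism of random model samples, measured as the mean
  (over many synthetic draws) of the distance to the nearest real test
  shape;
* a simple nearest-vertex **fitting** protocol against raw scans with a
  radial crop around the nose tip, summarized by cumulative error
  distribution (CED) curves;
* an **age-classification** demonstration that uses model coefficients as
  features for a pluggable linear classifier.

Generalization and specificity distances are computed in the
Procrustes-aligned model frame so trivial pose differences do not count
as model error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .align import procrustes_align
from .mesh import DemographicRecord, LandmarkSet, TriangleMesh
from .models import (BespokeModelSet, LinearModel, age_bin, AGE_BIN_LABELS,
                     instance, project, sample_random)


@dataclass
class CurveResult:
    """A named metric curve: y(x) with strictly increasing x."""

    x: np.ndarray
    y: np.ndarray
    metric: str
    model_key: str = "global"
    y_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.x.size != self.y.size:
            raise ValueError("x and y lengths differ")
        if self.x.size and (np.diff(self.x) <= 0).any():
            raise ValueError("x must be strictly increasing")
        if not np.isfinite(self.y).all():
            raise ValueError("non-finite metric value")

    def to_csv(self, path) -> None:
        import csv
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["x", self.metric]
            if self.y_std is not None:
                header.append(f"{self.metric}_std")
            w.writerow(header)
            for i in range(self.x.size):
                row = [f"{self.x[i]:.10g}", f"{self.y[i]:.10g}"]
                if self.y_std is not None:
                    row.append(f"{self.y_std[i]:.10g}")
                w.writerow(row)

    def plot(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.x, self.y, marker="o", ms=3, label=self.model_key)
        if self.y_std is not None:
            ax.fill_between(self.x, self.y - self.y_std, self.y + self.y_std,
                            alpha=0.2)
        ax.set_xlabel("components" if "compact" in self.metric
                      or "general" in self.metric else "threshold")
        ax.set_ylabel(self.metric)
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _per_vertex_mean_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(
        a.reshape(-1, 3) - b.reshape(-1, 3), axis=1).mean())


def compactness_curve(model: LinearModel | np.ndarray) -> CurveResult:
    """Percentage of total variance explained by the leading c components.

    The eigenvalue spectrum should come from an untruncated build (or one
    carrying its total variance) so the curve genuinely ends at 100%.
    """
    if isinstance(model, LinearModel):
        lam = model.eigenvalues
        total = model.total_variance or lam.sum()
    else:
        lam = np.asarray(model, float)
        total = lam.sum()
    y = 100.0 * np.cumsum(lam) / total
    return CurveResult(x=np.arange(1, lam.size + 1), y=y,
                       metric="compactness_pct")


def _align_to_model(shape_vec: np.ndarray, model: LinearModel) -> np.ndarray:
    tf = procrustes_align(shape_vec.reshape(-1, 3),
                          model.mean.reshape(-1, 3), allow_scale=True)
    return tf.apply(shape_vec.reshape(-1, 3)).reshape(-1)


def generalization_curve(
        model: LinearModel, test_shapes: Sequence[TriangleMesh | np.ndarray],
        components: Sequence[int] | None = None,
        bespoke: BespokeModelSet | None = None,
        records: Sequence[DemographicRecord] | None = None,
        align: bool = True) -> CurveResult:
    """Mean per-vertex reconstruction error of held-out shapes vs
    retained components.

    With ``bespoke`` (and per-shape ``records``), each test shape is
    projected on its demographically matched model instead of the global
    one; the x axis then indexes components of each routed model.
    """
    vecs = [s.as_vector() if isinstance(s, TriangleMesh)
            else np.asarray(s, float).reshape(-1) for s in test_shapes]
    if not vecs:
        raise ValueError("empty test set")
    for vv in vecs:
        if vv.size != model.mean.size:
            raise ValueError("test shape topology does not match the model")
    if components is None:
        components = list(range(1, model.n_components + 1))
    if bespoke is not None and records is None:
        raise ValueError("bespoke routing needs demographic records")
    ys = []
    routed = ([bespoke.select(r) for r in records]
              if bespoke is not None else [model] * len(vecs))
    aligned = [(_align_to_model(v, m) if align else v)
               for v, m in zip(vecs, routed)]
    for c in components:
        errs = [_per_vertex_mean_distance(
                    v, project(m, v, n_components=min(c, m.n_components))[1])
                for v, m in zip(aligned, routed)]
        ys.append(np.mean(errs))
    return CurveResult(x=np.asarray(components, float), y=np.asarray(ys),
                       metric="generalization_mm",
                       model_key="bespoke" if bespoke is not None
                       else "global")


def specificity(model: LinearModel,
                test_shapes: Sequence[TriangleMesh | np.ndarray],
                n_samples: int = 10000, components: int | None = None,
                seed: int | np.random.Generator = 0,
                align: bool = True) -> tuple[float, float]:
    """Mean ± sd over random synthetic instances of the distance to the
    nearest test shape (mean per-vertex metric)."""
    vecs = np.asarray([
        s.as_vector() if isinstance(s, TriangleMesh)
        else np.asarray(s, float).reshape(-1) for s in test_shapes])
    if len(vecs) == 0:
        raise ValueError("empty test set")
    if align:
        vecs = np.asarray([_align_to_model(v, model) for v in vecs])
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    test = vecs.reshape(len(vecs), -1, 3)
    dists = np.empty(n_samples)
    for i in range(n_samples):
        _, x = sample_random(model, rng, n_components=components)
        d = np.linalg.norm(test - x.reshape(1, -1, 3), axis=2).mean(axis=1)
        dists[i] = d.min()
    return float(dists.mean()), float(dists.std())


def radial_crop(scan: TriangleMesh, nosetip: np.ndarray, radius: float
                ) -> np.ndarray:
    """Mask of scan vertices within ``radius`` of the nose tip."""
    nosetip = np.asarray(nosetip, float).reshape(3)
    if not np.isfinite(nosetip).all():
        raise ValueError("nose-tip landmark is masked/non-finite")
    return np.linalg.norm(scan.points - nosetip, axis=1) <= radius


def default_crop_radius(scan_landmarks: LandmarkSet,
                        left_label: str = "eye_outer_l",
                        right_label: str = "eye_outer_r",
                        factor: float = 0.45) -> float:
    """Crop radius scaled to the scan: factor × inter-outer-eye-corner
    distance (resolution- and size-independent)."""
    d = np.linalg.norm(scan_landmarks[left_label]
                       - scan_landmarks[right_label])
    return float(factor * d)


def fit_to_scan(model: LinearModel, raw_scan: TriangleMesh,
                scan_landmarks: LandmarkSet, model_landmarks: LandmarkSet,
                components: int | None = None,
                crop_radius: float | None = None,
                nosetip_label: str = "nose_tip"
                ) -> tuple[TriangleMesh, np.ndarray]:
    """Nearest-vertex model fitting against a raw scan.

    The model mean is similarity-aligned to the scan through shared
    landmarks; each model vertex picks its nearest scan vertex to form a
    pseudo-correspondence vector, which is projected on the model
    subspace (truncated at ``components``).  Errors are reported in the
    scan frame, for every cropped scan vertex, as the distance to its
    nearest vertex of the fitted instance.

    Returns ``(fitted mesh in the scan frame, per-vertex errors over the
    crop)``.
    """
    mutual = scan_landmarks.valid_mask & model_landmarks.valid_mask
    if mutual.sum() < 3:
        raise ValueError("need >= 3 mutually valid landmarks")
    tf = procrustes_align(scan_landmarks.points[mutual],
                          model_landmarks.points[mutual], allow_scale=True)
    scan_in_model = tf.apply(raw_scan.points)
    scan_tree = cKDTree(scan_in_model)
    mean_pts = model.mean.reshape(-1, 3)
    _, nearest = scan_tree.query(mean_pts)
    pseudo = scan_in_model[nearest].reshape(-1)
    _, fitted_vec = project(model, pseudo, n_components=components)
    fitted_model_frame = fitted_vec.reshape(-1, 3)
    fitted_scan_frame = tf.inverse().apply(fitted_model_frame)

    if crop_radius is None:
        crop_radius = default_crop_radius(scan_landmarks)
    nosetip = scan_landmarks[nosetip_label]
    crop = radial_crop(raw_scan, nosetip, crop_radius)
    fit_tree = cKDTree(fitted_scan_frame)
    errors, _ = fit_tree.query(raw_scan.points[crop])
    return (TriangleMesh(fitted_scan_frame, model.trilist), errors)


def ced_curve(errors: np.ndarray, thresholds: np.ndarray | None = None
              ) -> CurveResult:
    """Cumulative error distribution: fraction of errors ≤ each
    threshold."""
    e = np.asarray(errors, float).reshape(-1)
    if (e < 0).any():
        raise ValueError("errors must be non-negative")
    if thresholds is None:
        hi = e.max() if e.size else 1.0
        thresholds = np.linspace(0.0, hi * 1.05 + 1e-12, 50)
    t = np.asarray(thresholds, float)
    y = np.asarray([(e <= ti).mean() for ti in t])
    return CurveResult(x=t, y=y, metric="ced_fraction")


# ---------------------------------------------------------------------------
# age classification demo

class LinearClassifier(Protocol):
    """fit/predict contract for the pluggable classifier seam."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> object: ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...


def age_class_demo(model: LinearModel,
                   shapes: Sequence[TriangleMesh | np.ndarray],
                   records: Sequence[DemographicRecord],
                   classifier: LinearClassifier,
                   test_fraction: float = 0.3,
                   seed: int = 0, align: bool = True) -> dict:
    """Classify four age bands from model coefficients.

    Features are the projection coefficients of each shape; classes the
    half-open age bins shared with the bespoke grouping.  Returns macro
    precision / recall / F-score plus the per-class table on a random
    held-out split.  Every class must appear in the training split.
    """
    if len(shapes) != len(records):
        raise ValueError("one demographic record per shape required")
    X = np.asarray([
        project(model, _align_to_model(
            s.as_vector() if isinstance(s, TriangleMesh)
            else np.asarray(s, float).reshape(-1), model) if align
            else (s.as_vector() if isinstance(s, TriangleMesh)
                  else np.asarray(s, float).reshape(-1)))[0]
        for s in shapes])
    y = np.asarray([age_bin(r.age) for r in records])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    n_test = max(1, int(round(test_fraction * len(X))))
    test_idx, train_idx = order[:n_test], order[n_test:]
    missing = [c for c in np.unique(y) if c not in y[train_idx]]
    if missing:
        raise ValueError(f"classes absent from training split: {missing}")
    if len(np.unique(y[test_idx])) < 2:
        raise ValueError("test split contains a single class")
    classifier.fit(X[train_idx], y[train_idx])
    pred = np.asarray(classifier.predict(X[test_idx]))
    truth = y[test_idx]
    per_class = {}
    precs, recs, fs = [], [], []
    for c in np.unique(y):
        tp = float(((pred == c) & (truth == c)).sum())
        fp = float(((pred == c) & (truth != c)).sum())
        fn = float(((pred != c) & (truth == c)).sum())
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        per_class[str(c)] = {"precision": p, "recall": r, "f_score": f,
                             "support": int((truth == c).sum())}
        precs.append(p); recs.append(r); fs.append(f)
    return {"macro_precision": float(np.mean(precs)),
            "macro_recall": float(np.mean(recs)),
            "macro_f": float(np.mean(fs)),
            "per_class": per_class,
            "n_train": int(len(train_idx)), "n_test": int(len(test_idx))}
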