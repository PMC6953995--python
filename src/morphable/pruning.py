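"""Chi-square plausibility pruning of failed correspondences.

Under the probabilistic reading of a PCA model the coefficients α_i are
independent zero-mean Gaussians with variance λ_i, so the squared
Mahalanobis distance

    F(α) = Σ_i α_i² / λ_i

follows a chi-square distribution with d degrees of freedom.  Registration
failures land far from the training bulk and show up as improbably large
F, so everything above the chi-square quantile θ_f = icdf(p_f) is flagged
and the model rebuilt from the survivors — one pass, no re-iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .models import LinearModel, build_pca, project

#: Components with eigenvalue below this fraction of the leading one are
#: excluded from the Mahalanobis sum and from the degrees of freedom.
EIGENVALUE_FLOOR_RATIO = 1e-12


@dataclass
class PruningReport:
    """Per-subject plausibility scores and the flagging decision."""

    subject_ids: list[str]
    scores: np.ndarray       # F(α) per subject, >= 0
    threshold: float         # θ_f
    p_f: float
    degrees_of_freedom: int

    @property
    def flagged(self) -> list[str]:
        return [sid for sid, s in zip(self.subject_ids, self.scores)
                if s > self.threshold]

    @property
    def flagged_mask(self) -> np.ndarray:
        return self.scores > self.threshold

    def summary(self) -> dict:
        return {"p_f": self.p_f, "threshold": self.threshold,
                "degrees_of_freedom": self.degrees_of_freedom,
                "n_subjects": len(self.subject_ids),
                "n_flagged": int(self.flagged_mask.sum()),
                "flagged": self.flagged}


def _effective_components(model: LinearModel) -> np.ndarray:
    lam = model.eigenvalues
    if lam.size == 0:
        raise ValueError("model has no components")
    keep = lam > EIGENVALUE_FLOOR_RATIO * lam[0]
    if not keep.any():
        raise ValueError("all eigenvalues below the numerical floor")
    return keep


def mahalanobis_sq(model: LinearModel, coeffs: np.ndarray) -> float:
    """Squared Mahalanobis distance F(α) = Σ α_i²/λ_i of a coefficient
    vector from the model mean.

    Components whose eigenvalue sits below the numerical floor are
    excluded from the sum (they carry no usable variance).
    """
    a = np.asarray(coeffs, dtype=np.float64).reshape(-1)
    if a.size != model.n_components:
        raise ValueError(f"expected {model.n_components} coefficients, "
                         f"got {a.size}")
    keep = _effective_components(model)
    return float(np.sum(a[keep] ** 2 / model.eigenvalues[keep]))


def chi2_threshold(d: int, p_f: float) -> float:
    """θ_f with CDF_{χ²_d}(θ_f) = p_f — the chi-square inverse CDF."""
    if d < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {d}")
    if not 0.0 < p_f < 1.0:
        raise ValueError(f"p_f must lie strictly in (0, 1), got {p_f}")
    return float(chi2.ppf(p_f, df=d))


def _power_cap(n: int, p_f: float) -> int:
    """Largest usable chi-square dimensionality for n training shapes.

    Scores against the sample covariance satisfy Σ_i F_i = d·(n−1), so no
    single shape — however extreme — can score much above n−1.  A
    threshold θ_f(d, p_f) beyond that has no detection power; capping d
    so that θ_f ≤ (n−1)/3 keeps a detection margin.  Immaterial at
    population scale (n in the thousands), binding only for small
    cohorts.
    """
    d = 1
    while chi2_threshold(d + 1, p_f) <= (n - 1) / 3.0:
        d += 1
    return d


def prune_and_rebuild(
        shapes, subject_ids: list[str] | None = None,
        p_f: float = 0.99, trilist=None,
        variance_to_retain: float | None = None,
        n_components: int | None = None,
) -> tuple[LinearModel, PruningReport]:
    """Two-pass model build: initial PCA on every corresponded shape,
    chi-square flagging of implausible fits, final PCA on the survivors.

    ``shapes`` may be TriangleMeshes (in correspondence) or flat vectors;
    ``trilist`` is required for flat vectors.  The initial PCA is
    truncated by the same rule as the final build, additionally capped at
    the dimensionality where the chi-square test retains detection power
    (see :func:`_power_cap`).  Single pass by design — flagged subjects
    are removed once and the model rebuilt.
    """
    from .mesh import TriangleMesh
    if trilist is None:
        if not (len(shapes) and isinstance(shapes[0], TriangleMesh)):
            raise ValueError("trilist required for vector inputs")
        trilist = shapes[0].trilist
    vecs = np.asarray([
        s.as_vector() if isinstance(s, TriangleMesh)
        else np.asarray(s, float).reshape(-1) for s in shapes])
    k = len(vecs)
    if k < 3:
        raise ValueError(f"pruning needs at least 3 shapes, got {k}")
    if subject_ids is None:
        subject_ids = [f"subject_{i:05d}" for i in range(k)]

    initial = build_pca(vecs, trilist,
                        variance_to_retain=variance_to_retain,
                        n_components=n_components)
    initial = initial.truncated(
        min(initial.n_components, _power_cap(k, p_f)))
    keep = _effective_components(initial)
    d = int(keep.sum())
    theta = chi2_threshold(d, p_f)
    scores = np.array([
        mahalanobis_sq(initial, project(initial, v)[0]) for v in vecs])
    report = PruningReport(subject_ids=list(subject_ids), scores=scores,
                           threshold=theta, p_f=p_f, degrees_of_freedom=d)
    survivors = vecs[~report.flagged_mask]
    if len(survivors) < 2:
        raise ValueError(
            f"pruning at p_f={p_f} would leave {len(survivors)} < 2 shapes")
    final = build_pca(survivors, trilist,
                      variance_to_retain=variance_to_retain,
                      n_components=n_components)
    return final, report


def write_report_csv(report: PruningReport, path) -> None:
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "F", "flagged"])
        for sid, s, fl in zip(report.subject_ids, report.scores,
                              report.flagged_mask):
            w.writerow([sid, f"{s:.10g}", int(fl)])
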