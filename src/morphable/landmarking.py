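"""Automatic 3D landmarking by rendered-view back-projection.

A scan is rendered from a rig of virtual cameras; a pluggable 2D landmark
localizer runs on each texture view; the per-pixel XYZ shape images lift
the 2D detections to 3D; and the per-view results are composited into one
master annotation by keeping, per landmark, the most confident valid
candidate across views.  Any 2D detector honouring the
:class:`Detector2D` contract can be plugged in — the package ships an
oracle detector for synthetic data (see :mod:`morphable.fixtures`) and
loads external ones by dotted path.
"""

from __future__ import annotations

import importlib
import logging
from typing import Protocol, Sequence

import numpy as np

from .mesh import LandmarkSet, TriangleMesh
from .rendering import RenderedView, VirtualCamera, render_views

log = logging.getLogger(__name__)


class Detector2D(Protocol):
    """2D landmark localizer contract.

    Called with a rendered view; must return ``(pixels, confidences)``
    where ``pixels`` is L×2 ``(u, v)`` coordinates (sub-pixel allowed) and
    ``confidences`` are in [0, 1], with L the configured landmark count.
    """

    labels: Sequence[str]

    def __call__(self, view: RenderedView
                 ) -> tuple[np.ndarray, np.ndarray]: ...


def load_detector(dotted_path: str, **kwargs) -> Detector2D:
    """Instantiate a detector plug-in from ``"module.sub:factory"``."""
    mod_name, _, attr = dotted_path.partition(":")
    factory = getattr(importlib.import_module(mod_name), attr)
    return factory(**kwargs)


def backproject_landmarks(view: RenderedView, pixels: np.ndarray,
                          labels: Sequence[str],
                          confidences: np.ndarray | None = None
                          ) -> LandmarkSet:
    """Lift 2D detections to 3D via the view's XYZ shape image.

    Sub-pixel locations are resolved by bilinear interpolation over the
    covered pixels among the 4 neighbours (weights renormalized); a
    detection whose neighbourhood is entirely off-surface is returned
    masked rather than raising.
    """
    h, w = view.coverage_mask.shape
    px = np.atleast_2d(np.asarray(pixels, float))
    L = len(px)
    if confidences is None:
        confidences = np.ones(L)
    points = np.full((L, 3), np.nan)
    valid = np.zeros(L, dtype=bool)
    for i, (u, v) in enumerate(px):
        if not (0 <= u <= w - 1 and 0 <= v <= h - 1):
            continue
        c0, r0 = int(np.floor(u)), int(np.floor(v))
        c1, r1 = min(c0 + 1, w - 1), min(r0 + 1, h - 1)
        fu, fv = u - c0, v - r0
        corners = [(r0, c0, (1 - fu) * (1 - fv)), (r0, c1, fu * (1 - fv)),
                   (r1, c0, (1 - fu) * fv), (r1, c1, fu * fv)]
        wsum, acc = 0.0, np.zeros(3)
        for r, c, wgt in corners:
            if view.coverage_mask[r, c] and wgt > 0:
                acc += wgt * view.shape_image[r, c]
                wsum += wgt
        if wsum > 0:
            points[i] = acc / wsum
            valid[i] = True
    return LandmarkSet(labels=list(labels), points=points, valid_mask=valid,
                       confidences=np.asarray(confidences, float))


def composite_landmarks(per_view: Sequence[LandmarkSet]) -> LandmarkSet:
    """Per label, keep the valid candidate of maximal confidence (ties go
    to the earliest view in rig order); no valid candidate → masked."""
    if not per_view:
        raise ValueError("no per-view landmark sets to composite")
    labels = list(per_view[0].labels)
    for lms in per_view[1:]:
        if list(lms.labels) != labels:
            raise ValueError("per-view landmark sets disagree on labels")
    L = len(labels)
    points = np.full((L, 3), np.nan)
    valid = np.zeros(L, dtype=bool)
    conf = np.zeros(L)
    for i in range(L):
        best = -1.0
        for lms in per_view:
            c = 1.0 if lms.confidences is None else float(lms.confidences[i])
            if lms.valid_mask[i] and c > best:  # strict: ties keep earlier
                best, points[i], valid[i] = c, lms.points[i], True
        conf[i] = max(best, 0.0)
    return LandmarkSet(labels=labels, points=points, valid_mask=valid,
                       confidences=conf)


def auto_landmark(mesh: TriangleMesh, cameras: Sequence[VirtualCamera],
                  detector: Detector2D) -> LandmarkSet:
    """Render → detect per view → back-project → composite.

    A detector failure on one view skips that view with a warning; all
    views failing is an error.
    """
    views = render_views(mesh, list(cameras))
    per_view = []
    for k, view in enumerate(views):
        if view.is_empty:
            log.warning("view %d has zero coverage; skipped", k)
            continue
        try:
            pixels, confidences = detector(view)
        except Exception:
            log.warning("detector failed on view %d; skipped", k,
                        exc_info=True)
            continue
        lms = backproject_landmarks(view, pixels, detector.labels,
                                    confidences)
        # a zero-confidence detection is no detection
        lms.valid_mask &= lms.confidences > 0
        per_view.append(lms)
    if not per_view:
        raise RuntimeError("landmark detection failed on every view")
    return composite_landmarks(per_view)
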