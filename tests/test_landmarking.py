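"""Back-projection landmarking: lift, composite, end-to-end recovery."""

import numpy as np
import pytest

import morphable as M
from morphable.fixtures import FixtureSpec, generate_population, oracle_detector
from morphable.landmarking import (auto_landmark, backproject_landmarks,
                                   composite_landmarks)
from morphable.rendering import RenderedView, VirtualCamera


def synthetic_view(h=8, w=8):
    cam = VirtualCamera(position=np.zeros(3), rotation=np.eye(3),
                        focal=(10.0, 10.0), principal=(3.5, 3.5),
                        image_shape=(h, w))
    shape = np.full((h, w, 3), np.nan)
    cover = np.zeros((h, w), dtype=bool)
    return RenderedView(texture_image=np.zeros((h, w, 3)),
                        shape_image=shape, coverage_mask=cover, camera=cam)


class TestBackproject:
    def test_integer_pixel_returns_that_xyz(self):
        view = synthetic_view()
        view.shape_image[3, 5] = [1.0, 2.0, 3.0]
        view.coverage_mask[3, 5] = True
        lms = backproject_landmarks(view, [[5.0, 3.0]], ["a"])
        assert lms.valid_mask[0]
        np.testing.assert_allclose(lms.points[0], [1, 2, 3])

    def test_center_of_four_covered_neighbours_is_their_mean(self):
        view = synthetic_view()
        vals = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]],
                        dtype=float)
        for (r, c), v in zip([(2, 2), (2, 3), (3, 2), (3, 3)], vals):
            view.shape_image[r, c] = v
            view.coverage_mask[r, c] = True
        lms = backproject_landmarks(view, [[2.5, 2.5]], ["a"])
        np.testing.assert_allclose(lms.points[0], vals.mean(axis=0))

    def test_partially_covered_neighbourhood_renormalizes(self):
        view = synthetic_view()
        view.shape_image[2, 2] = [4.0, 4.0, 4.0]
        view.coverage_mask[2, 2] = True
        lms = backproject_landmarks(view, [[2.4, 2.4]], ["a"])
        assert lms.valid_mask[0]
        np.testing.assert_allclose(lms.points[0], [4, 4, 4])

    def test_background_pixel_masked_not_error(self):
        view = synthetic_view()
        lms = backproject_landmarks(view, [[4.0, 4.0], [100.0, 2.0]],
                                    ["a", "b"])
        assert not lms.valid_mask.any()


class TestComposite:
    def lmset(self, pts, valid, conf):
        return M.LandmarkSet(labels=["x", "y"], points=pts,
                             valid_mask=valid, confidences=conf)

    def test_single_view_passes_through(self):
        a = self.lmset([[1, 1, 1], [2, 2, 2]], [True, True], [0.5, 0.9])
        out = composite_landmarks([a])
        np.testing.assert_array_equal(out.points, a.points)

    def test_argmax_confidence_wins(self):
        a = self.lmset([[1, 0, 0], [1, 0, 0]], [True, True], [0.9, 0.4])
        b = self.lmset([[2, 0, 0], [2, 0, 0]], [True, True], [0.4, 0.8])
        out = composite_landmarks([a, b])
        assert out.points[0, 0] == 1.0 and out.points[1, 0] == 2.0

    def test_tie_goes_to_earlier_view(self):
        a = self.lmset([[1, 0, 0], [1, 0, 0]], [True, True], [0.7, 0.7])
        b = self.lmset([[2, 0, 0], [2, 0, 0]], [True, True], [0.7, 0.7])
        out = composite_landmarks([a, b])
        np.testing.assert_array_equal(out.points[:, 0], [1.0, 1.0])

    def test_invalid_everywhere_is_masked(self):
        a = self.lmset([[1, 0, 0], [np.nan] * 3], [True, False], [0.9, 0.0])
        b = self.lmset([[1, 0, 0], [np.nan] * 3], [True, False], [0.9, 0.0])
        out = composite_landmarks([a, b])
        assert out.valid_mask[0] and not out.valid_mask[1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            composite_landmarks([])

    def test_label_mismatch_rejected(self):
        a = self.lmset([[0] * 3, [0] * 3], [True, True], [1, 1])
        b = M.LandmarkSet(labels=["p", "q"], points=np.zeros((2, 3)),
                          confidences=np.ones(2))
        with pytest.raises(ValueError):
            composite_landmarks([a, b])


@pytest.fixture(scope="module")
def dense_subject():
    spec = FixtureSpec(n_subjects=1, seed=5, noise_sd=0.0,
                       remesh_points=12000)
    return generate_population(spec)[0]


class TestAutoLandmark:
    def test_oracle_recovery_within_pixel_footprint(self, dense_subject):
        """End-to-end: rendered-view landmarking recovers ground truth to
        within each landmark's one-pixel surface footprint (depth/f
        divided by the cosine of the viewing incidence)."""
        s = dense_subject
        cams = M.default_camera_rig(s.raw, image_shape=(512, 512))
        det = oracle_detector(s)
        views = M.render_views(s.raw, cams)
        lms = auto_landmark(s.raw, cams, det)
        assert lms.valid_mask.sum() >= 0.9 * len(lms)
        surf = M.SurfaceIndex(s.raw)
        for i in range(len(lms)):
            if not lms.valid_mask[i]:
                continue
            err = np.linalg.norm(lms.points[i] - s.landmarks.points[i])
            for v in views:
                _, conf = det(v)
                if conf[i] == 1.0:  # composite keeps the earliest view
                    z = v.camera.to_camera(
                        s.landmarks.points[i][None])[0, 2]
                    _, _, tri = surf.closest_points(
                        s.landmarks.points[i][None])
                    tv = s.raw.triangles[tri[0]]
                    n = np.cross(tv[1] - tv[0], tv[2] - tv[0])
                    n /= np.linalg.norm(n)
                    ray = s.landmarks.points[i] - v.camera.position
                    ray /= np.linalg.norm(ray)
                    footprint = (z / v.camera.focal[0]) / max(
                        abs(n @ ray), 0.05)
                    assert err <= footprint
                    break

    def test_zero_confidence_detector_masks_everything(self, dense_subject):
        s = dense_subject
        cams = M.default_camera_rig(s.raw, image_shape=(128, 128))

        class NullDetector:
            labels = list(s.landmarks.labels)

            def __call__(self, view):
                px, _ = view.camera.project(s.landmarks.points)
                return px, np.zeros(len(px))

        lms = auto_landmark(s.raw, cams, NullDetector())
        assert not lms.valid_mask.any()

    def test_occluded_landmarks_fall_back_to_other_views(self,
                                                         dense_subject):
        """In a strong profile view the far side of the face is hidden;
        the composite must still recover those landmarks from the other
        cameras."""
        s = dense_subject
        cams = M.default_camera_rig(s.raw, image_shape=(256, 256),
                                    yaw_angles_deg=(80.0, 0.0))
        det = oracle_detector(s)
        views = M.render_views(s.raw, cams)
        confs = np.array([det(v)[1] for v in views])
        occluded = (confs[0] == 0.0) & (confs[1] == 1.0)
        assert occluded.sum() > 0  # far-side points really are hidden
        lms = auto_landmark(s.raw, cams, det)
        assert lms.valid_mask[occluded].all()

    def test_failing_detector_view_is_skipped(self, dense_subject):
        s = dense_subject
        cams = M.default_camera_rig(s.raw, image_shape=(128, 128),
                                    yaw_angles_deg=(0.0, 30.0))
        calls = {"n": 0}
        inner = oracle_detector(s)

        class Flaky:
            labels = inner.labels

            def __call__(self, view):
                calls["n"] += 1
                if calls["n"] == 1:
                    raise RuntimeError("detector crashed")
                return inner(view)

        lms = auto_landmark(s.raw, cams, Flaky())
        assert lms.valid_mask.sum() > 0

    def test_all_views_failing_is_an_error(self, dense_subject):
        s = dense_subject
        cams = M.default_camera_rig(s.raw, image_shape=(64, 64),
                                    yaw_angles_deg=(0.0,))

        class Broken:
            labels = ["a"]

            def __call__(self, view):
                raise RuntimeError("no detections")

        with pytest.raises(RuntimeError, match="every view"):
            auto_landmark(s.raw, cams, Broken())

    def test_composited_landmarks_lie_on_surface(self, dense_subject):
        s = dense_subject
        cams = M.default_camera_rig(s.raw, image_shape=(256, 256))
        lms = auto_landmark(s.raw, cams, oracle_detector(s))
        surf = M.SurfaceIndex(s.raw)
        _, d, _ = surf.closest_points(lms.points[lms.valid_mask])
        # on-surface to within a pixel footprint at the rig distance
        cam = cams[0]
        z = cam.to_camera(s.raw.points.mean(0)[None])[0, 2]
        assert d.max() <= z / cam.focal[0]
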