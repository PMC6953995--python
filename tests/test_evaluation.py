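"""Model evaluation battery: compactness, generalization, specificity,
fitting, CED, age classification."""

import numpy as np
import pytest
from sklearn.svm import LinearSVC

import morphable as M
from morphable.evaluation import (ced_curve, compactness_curve,
                                  default_crop_radius, fit_to_scan,
                                  generalization_curve, radial_crop,
                                  specificity, age_class_demo)
from morphable.fixtures import (DemographicGroup, FixtureSpec,
                                generate_population)
from morphable.models import build_pca, instance, sample_random

TRIS = np.array([[0, 1, 2], [1, 2, 3]])


def toy_model(rng, d=4, n_pts=4):
    return build_pca(rng.normal(0, 2, (14, 3 * n_pts)), TRIS,
                     n_components=d)


class TestCompactness:
    def test_reaches_exactly_100(self, rng):
        c = compactness_curve(rng.uniform(0.1, 5, 6))
        assert c.y[-1] == pytest.approx(100.0, abs=1e-9)
        assert (np.diff(c.y) >= 0).all()

    def test_equal_eigenvalues_half_at_half(self):
        c = compactness_curve(np.ones(10))
        assert c.y[4] == pytest.approx(50.0)

    def test_matches_cumulative_sum_oracle(self, rng):
        lam = np.sort(rng.uniform(0.01, 9, 8))[::-1]
        c = compactness_curve(lam)
        np.testing.assert_allclose(c.y, 100 * np.cumsum(lam) / lam.sum())


class TestGeneralization:
    def test_training_set_with_full_basis_is_zero(self, rng):
        X = rng.normal(0, 2, (6, 12))
        model = build_pca(X, TRIS)
        g = generalization_curve(model, list(X), align=False)
        assert g.y[-1] == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_noise_error_independent_of_components(self, rng):
        model = toy_model(rng, d=2)
        # residual orthogonal to the subspace
        noise = rng.normal(0, 1, model.mean.size)
        noise -= model.basis @ (model.basis.T @ noise)
        test = model.mean + noise
        g = generalization_curve(model, [test], components=[1, 2],
                                 align=False)
        assert g.y[0] == pytest.approx(g.y[1], rel=1e-9)

    def test_non_increasing_in_components(self, rng):
        model = toy_model(rng)
        tests = [rng.normal(0, 3, model.mean.size) for _ in range(5)]
        g = generalization_curve(model, tests, align=False)
        assert (np.diff(g.y) <= 1e-10).all()
        # brute-force per-c check against explicit projections
        for ci, c in enumerate(g.x.astype(int)):
            errs = []
            U = model.basis[:, :c]
            for t in tests:
                rec = model.mean + U @ (U.T @ (t - model.mean))
                errs.append(np.linalg.norm(
                    (t - rec).reshape(-1, 3), axis=1).mean())
            assert g.y[ci] == pytest.approx(np.mean(errs), rel=1e-9)

    def test_topology_mismatch_rejected(self, rng):
        model = toy_model(rng)
        with pytest.raises(ValueError):
            generalization_curve(model, [np.zeros(model.mean.size + 3)])

    def test_bespoke_routing_uses_matched_model(self, rng):
        young = build_pca(rng.normal(0, 1, (8, 12)) + 10, TRIS)
        old = build_pca(rng.normal(0, 1, (8, 12)) - 10, TRIS)
        bset = M.BespokeModelSet(
            rules=[(lambda r: r.age < 18, "young"),
                   (lambda r: True, "old")],
            models={"young": young, "old": old, "global": young})
        recs = [M.DemographicRecord("a", 5, "f", "x"),
                M.DemographicRecord("b", 60, "m", "x")]
        tests = [young.mean, old.mean]
        g = generalization_curve(young, tests, components=[1],
                                 bespoke=bset, records=recs, align=False)
        assert g.y[0] == pytest.approx(0.0, abs=1e-9)


class TestSpecificity:
    def test_degenerate_model_against_its_mean_is_zero(self, rng):
        model = toy_model(rng)
        frozen = M.LinearModel(model.mean, model.basis,
                               np.zeros(model.n_components), TRIS)
        mean, sd = specificity(frozen, [frozen.mean], n_samples=10,
                               seed=0, align=False)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_single_candidate_nearest_neighbour_distance(self, rng):
        model = toy_model(rng)
        frozen = M.LinearModel(model.mean, model.basis,
                               np.zeros(model.n_components), TRIS)
        v = rng.normal(0, 1, model.mean.size)
        mean, _ = specificity(frozen, [model.mean + v], n_samples=5,
                              seed=0, align=False)
        expect = np.linalg.norm(v.reshape(-1, 3), axis=1).mean()
        assert mean == pytest.approx(expect, rel=1e-9)

    def test_monte_carlo_stability_across_seeds(self, rng):
        model = toy_model(rng)
        tests = [rng.normal(0, 2, model.mean.size) for _ in range(8)]
        m1, s1 = specificity(model, tests, n_samples=100, seed=1,
                             align=False)
        m2, _ = specificity(model, tests, n_samples=100, seed=2,
                            align=False)
        # difference of two independent 100-sample means
        assert abs(m1 - m2) <= 3.0 * s1 * np.sqrt(2.0 / 100)

    def test_empty_test_set_rejected(self, rng):
        with pytest.raises(ValueError):
            specificity(toy_model(rng), [], n_samples=5)


class TestRadialCrop:
    def test_zero_radius_keeps_only_coincident_vertices(self, template):
        tmpl, tlms = template
        nose = tlms["nose_tip"]
        mask = radial_crop(tmpl, nose, 0.0)
        assert mask.sum() == 1

    def test_huge_radius_keeps_everything(self, template):
        tmpl, tlms = template
        mask = radial_crop(tmpl, tlms["nose_tip"], 1e6)
        assert mask.all()

    def test_count_matches_brute_force(self, template, rng):
        tmpl, tlms = template
        nose = tlms["nose_tip"]
        for r in (10.0, 35.0, 70.0):
            mask = radial_crop(tmpl, nose, r)
            brute = np.array([np.linalg.norm(p - nose) <= r
                              for p in tmpl.points])
            np.testing.assert_array_equal(mask, brute)

    def test_masked_nosetip_rejected(self, template):
        tmpl, _ = template
        with pytest.raises(ValueError):
            radial_crop(tmpl, np.array([np.nan] * 3), 10.0)


class TestCed:
    def test_extremes(self, rng):
        e = rng.uniform(0.1, 2.0, 50)
        c = ced_curve(e, thresholds=[0.0, e.max()])
        assert c.y[0] == 0.0 and c.y[-1] == 1.0

    def test_matches_empirical_cdf_oracle(self, rng):
        e = rng.exponential(1.0, 200)
        ts = np.linspace(0, 5, 20)
        c = ced_curve(e, thresholds=ts)
        ref = [(np.sort(e) <= t).sum() / e.size for t in ts]
        np.testing.assert_allclose(c.y, ref)

    def test_negative_errors_rejected(self):
        with pytest.raises(ValueError):
            ced_curve(np.array([-0.1, 0.5]))


@pytest.fixture(scope="module")
def face_model():
    spec = FixtureSpec(n_subjects=40, seed=31, noise_sd=0.0,
                       remesh=False, rigid_rot_deg=0.0,
                       rigid_trans_mm=0.0,
                       demographics=(DemographicGroup("A", 1.0, 0.0),))
    pop = generate_population(spec)
    meshes = [s.ground_truth for s in pop]
    aligned, _ = M.generalized_procrustes(meshes)
    model = build_pca([m.as_vector() for m in aligned],
                      meshes[0].trilist, variance_to_retain=0.999)
    return model, pop[0]


class TestFitToScan:
    def model_landmarks(self, model, tlms):
        return M.LandmarkSet(labels=tlms.labels,
                             points=model.mean.reshape(-1, 3)[
                                 tlms.template_indices],
                             template_indices=tlms.template_indices)

    def test_scan_equal_to_mean_fits_exactly(self, face_model, template):
        model, _ = face_model
        _, tlms = template
        scan = model.mean_mesh()
        mlms = self.model_landmarks(model, tlms)
        slms = M.LandmarkSet(labels=tlms.labels,
                             points=scan.points[tlms.template_indices])
        fitted, errors = fit_to_scan(model, scan, slms, mlms)
        assert errors.max() < 1e-6

    def test_in_subspace_scan_fits_to_noise_floor(self, face_model,
                                                  template):
        model, _ = face_model
        _, tlms = template
        alpha = np.zeros(model.n_components)
        alpha[0] = np.sqrt(model.eigenvalues[0])
        scan = instance(model, alpha)
        mlms = self.model_landmarks(model, tlms)
        slms = M.LandmarkSet(labels=tlms.labels,
                             points=scan.points[tlms.template_indices])
        _, errors = fit_to_scan(model, scan, slms, mlms)
        # the landmark-subset similarity alignment of the protocol is not
        # exactly the subspace's own frame, leaving a sub-mm floor even
        # for a perfectly representable target (face scale ~160 mm)
        assert errors.mean() < 1.0

    def test_errors_match_independent_projection_oracle(self, face_model,
                                                        template):
        from scipy.spatial import cKDTree
        from morphable.align import procrustes_align
        model, subj = face_model
        _, tlms = template
        scan = subj.raw
        slms = subj.landmarks
        mlms = self.model_landmarks(model, tlms)
        fitted, errors = fit_to_scan(model, scan, slms, mlms,
                                     components=5)
        # oracle: replay the protocol with independent code
        mutual = slms.valid_mask & mlms.valid_mask
        tf = procrustes_align(slms.points[mutual], mlms.points[mutual])
        scan_m = tf.apply(scan.points)
        nearest = cKDTree(scan_m).query(model.mean.reshape(-1, 3))[1]
        pseudo = scan_m[nearest].reshape(-1)
        U = model.basis[:, :5]
        rec = model.mean + U @ (U.T @ (pseudo - model.mean))
        fit_scan = tf.inverse().apply(rec.reshape(-1, 3))
        crop = radial_crop(scan, slms["nose_tip"],
                           default_crop_radius(slms))
        ref = cKDTree(fit_scan).query(scan.points[crop])[0]
        np.testing.assert_allclose(errors, ref, atol=1e-9)


class TestAgeClassification:
    def separable_population(self):
        spec = FixtureSpec(n_subjects=120, seed=3, noise_sd=0.05,
                           remesh=False, rigid_rot_deg=0.0,
                           rigid_trans_mm=0.0, age_coupling=60.0,
                           demographics=(DemographicGroup(
                               "A", 1.0, 0.0, age_range=(0.5, 80.0)),))
        pop = generate_population(spec)
        meshes = [s.ground_truth for s in pop]
        model = build_pca([m.as_vector() for m in meshes],
                          meshes[0].trilist, n_components=5)
        return model, meshes, [s.record for s in pop]

    def test_age_coupled_modes_classify_well(self):
        model, meshes, records = self.separable_population()
        out = age_class_demo(model, meshes, records,
                             LinearSVC(), seed=0, align=False)
        assert out["macro_f"] > 0.9

    def test_shuffled_labels_fall_to_chance(self):
        model, meshes, records = self.separable_population()
        rng = np.random.default_rng(1)
        ages = np.array([r.age for r in records])
        rng.shuffle(ages)
        shuffled = [M.DemographicRecord(r.subject_id, a, r.gender,
                                        r.ethnicity)
                    for r, a in zip(records, ages)]
        out = age_class_demo(model, meshes, shuffled, LinearSVC(),
                             seed=0, align=False)
        assert out["macro_f"] < 0.55

    def test_missing_class_in_training_split_rejected(self):
        model, meshes, records = self.separable_population()
        young_only = [M.DemographicRecord(r.subject_id, 3.0, r.gender,
                                          r.ethnicity) for r in records]
        with pytest.raises(ValueError):
            age_class_demo(model, meshes, young_only, LinearSVC(), seed=0,
                           align=False)


class TestCurveResult:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            M.CurveResult(x=[1.0, 1.0], y=[0.0, 1.0], metric="m")
        with pytest.raises(ValueError):
            M.CurveResult(x=[1.0, 2.0], y=[0.0, np.nan], metric="m")

    def test_csv_round_trip(self, tmp_path):
        c = M.CurveResult(x=[1.0, 2.0, 3.0], y=[0.5, 0.25, 0.1],
                          metric="generalization_mm")
        p = tmp_path / "curve.csv"
        c.to_csv(p)
        rows = p.read_text().strip().splitlines()
        assert rows[0] == "x,generalization_mm"
        assert len(rows) == 4
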