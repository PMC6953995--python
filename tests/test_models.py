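"""PCA shape/texture models: build, project, sample, route, persist."""

import numpy as np
import pytest

import morphable as M
from morphable.fixtures import (DemographicGroup, FixtureSpec,
                                generate_population, true_mode_matrix)
from morphable.models import (AGE_BIN_LABELS, age_bin, build_pca,
                              default_bespoke_rules, instance, load_model,
                              project, sample_random, save_model,
                              transfer_color)

TRIS = np.array([[0, 1, 2], [1, 2, 3]])


def toy_model(rng, n_pts=4, d=3):
    samples = rng.normal(0, 2, (12, 3 * n_pts))
    return build_pca(samples, TRIS, n_components=d)


class TestBuildPca:
    def test_eigenvalues_match_dense_covariance(self, rng):
        X = rng.normal(0, 1, (5, 12))  # k=5, n=4 vertices
        model = build_pca(X, TRIS)
        cov = np.cov(X.T, ddof=1)
        ref = np.sort(np.linalg.eigvalsh(cov))[::-1][:model.n_components]
        np.testing.assert_allclose(model.eigenvalues, ref, atol=1e-8)

    def test_collinear_samples_give_one_component(self, rng):
        direction = rng.normal(size=12)
        X = np.outer(rng.normal(size=8), direction) + 5.0
        model = build_pca(X, TRIS)
        assert model.n_components == 1
        for x in X:
            _, rec = project(model, x)
            np.testing.assert_allclose(rec, x, atol=1e-8)

    def test_full_variance_reconstructs_training_set(self, rng):
        X = rng.normal(0, 3, (7, 12))
        model = build_pca(X, TRIS, variance_to_retain=1.0)
        for x in X:
            _, rec = project(model, x)
            np.testing.assert_allclose(rec, x, atol=1e-8)

    def test_basis_orthonormal_and_eigenvalues_sorted(self, rng):
        model = toy_model(rng)
        d = model.n_components
        np.testing.assert_allclose(model.basis.T @ model.basis, np.eye(d),
                                   atol=1e-8)
        assert (np.diff(model.eigenvalues) <= 1e-12).all()

    def test_sign_convention_is_deterministic(self, rng):
        X = rng.normal(0, 1, (6, 12))
        m1 = build_pca(X, TRIS)
        m2 = build_pca(X[::-1].copy()[::-1], TRIS)
        np.testing.assert_array_equal(m1.basis, m2.basis)
        cols = np.abs(m1.basis).argmax(axis=0)
        assert (m1.basis[cols, np.arange(m1.n_components)] > 0).all()

    def test_fewer_than_two_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            build_pca(rng.normal(size=(1, 12)), TRIS)

    def test_subspace_recovery_from_known_modes(self):
        """Parameter recovery: 200 draws from a known 5-mode generator,
        noise at 1% of mode scale, principal angles < 2 degrees."""
        spec = FixtureSpec(
            n_subjects=200, seed=5, noise_sd=0.01 * 3.0, remesh=False,
            rigid_rot_deg=0.0, rigid_trans_mm=0.0,
            demographics=(DemographicGroup("A", 1.0, 0.0),))
        pop = generate_population(spec)
        model = build_pca([s.raw.as_vector() for s in pop],
                          pop[0].raw.trilist, n_components=5)
        true_basis = np.linalg.qr(true_mode_matrix(spec))[0]
        s = np.linalg.svd(true_basis.T @ model.basis, compute_uv=False)
        angles = np.degrees(np.arccos(np.clip(s, -1, 1)))
        assert angles.max() < 2.0


class TestProjectInstance:
    def test_zero_coeffs_give_mean(self, rng):
        model = toy_model(rng)
        np.testing.assert_allclose(
            instance(model, np.zeros(model.n_components)).as_vector(),
            model.mean)

    def test_unit_coeff_moves_along_eigenvector(self, rng):
        model = toy_model(rng)
        c = 2.5
        out = instance(model, [0.0, c]).as_vector()
        np.testing.assert_allclose(out, model.mean + c * model.basis[:, 1],
                                   atol=1e-12)

    def test_project_of_instance_recovers_coefficients(self, rng):
        model = toy_model(rng)
        a0 = rng.normal(size=model.n_components)
        alpha, _ = project(model, instance(model, a0).as_vector())
        np.testing.assert_allclose(alpha, a0, atol=1e-10)

    def test_projection_matches_least_squares_oracle(self, rng):
        model = toy_model(rng)
        for _ in range(100):
            x = rng.normal(0, 4, model.mean.size)
            alpha, rec = project(model, x)
            a_ref, *_ = np.linalg.lstsq(model.basis, x - model.mean,
                                        rcond=None)
            np.testing.assert_allclose(alpha, a_ref, atol=1e-8)
            np.testing.assert_allclose(rec, model.mean + model.basis @ a_ref,
                                       atol=1e-8)

    def test_projection_idempotent(self, rng):
        model = toy_model(rng)
        x = rng.normal(0, 4, model.mean.size)
        _, p1 = project(model, x)
        _, p2 = project(model, p1)
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_reconstruction_error_non_increasing_in_components(self, rng):
        model = toy_model(rng, d=3)
        x = rng.normal(0, 4, model.mean.size)
        errs = [np.linalg.norm(x - project(model, x, n_components=c)[1])
                for c in range(model.n_components + 1)]
        assert (np.diff(errs) <= 1e-10).all()

    def test_too_many_coefficients_rejected(self, rng):
        model = toy_model(rng)
        with pytest.raises(ValueError):
            instance(model, np.zeros(model.n_components + 1))

    def test_length_mismatch_rejected(self, rng):
        model = toy_model(rng)
        with pytest.raises(ValueError):
            project(model, np.zeros(model.mean.size + 3))


class TestSampleRandom:
    def test_zero_eigenvalues_always_mean(self, rng):
        model = toy_model(rng)
        degenerate = M.LinearModel(model.mean, model.basis,
                                   np.zeros(model.n_components), TRIS)
        _, x = sample_random(degenerate, 123)
        np.testing.assert_array_equal(x, degenerate.mean)

    def test_same_seed_reproduces(self, rng):
        model = toy_model(rng)
        a1, x1 = sample_random(model, 7)
        a2, x2 = sample_random(model, 7)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(x1, x2)

    def test_component_variance_matches_eigenvalues(self, rng):
        model = toy_model(rng)
        g = np.random.default_rng(0)
        draws = np.array([sample_random(model, g)[0]
                          for _ in range(10_000)])
        assert draws[:, 0].var() == pytest.approx(model.eigenvalues[0],
                                                  rel=0.05)


class TestTransferColor:
    def test_point_at_vertex_gets_vertex_color(self, rng):
        mesh = M.TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]],
                              colors=[[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        out = transfer_color(mesh, mesh.points[1])
        np.testing.assert_allclose(out[0], [0, 1, 0], atol=1e-9)

    def test_centroid_gets_mean_color(self):
        mesh = M.TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]],
                              colors=[[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        out = transfer_color(mesh, mesh.points.mean(axis=0))
        np.testing.assert_allclose(out[0], [1 / 3] * 3, atol=1e-9)

    def test_uniform_color_everywhere(self, rng):
        mesh = M.TriangleMesh(rng.normal(size=(4, 3)), TRIS,
                              colors=np.full((4, 3), 0.37))
        out = transfer_color(mesh, rng.normal(size=(5, 3)))
        np.testing.assert_allclose(out, 0.37, atol=1e-9)


class TestBespoke:
    def make_set(self, rng):
        model = toy_model(rng)
        rules = default_bespoke_rules()
        keys = {k for _, k in rules} | {"global"}
        return M.BespokeModelSet(rules=rules,
                                 models={k: model for k in keys})

    def test_age_routing_within_ethnicity(self, rng):
        bset = self.make_set(rng)
        rec = M.DemographicRecord("s", age=30, gender="f", ethnicity="White")
        assert bset.select_key(rec) == "White-18-to-50"

    def test_age_edge_is_half_open(self, rng):
        bset = self.make_set(rng)
        rec = M.DemographicRecord("s", age=18, gender="m", ethnicity="White")
        assert bset.select_key(rec) == "White-18-to-50"
        assert age_bin(17.999) == "7-to-18"

    def test_plain_ethnicity_routes_regardless_of_age(self, rng):
        bset = self.make_set(rng)
        rec = M.DemographicRecord("s", age=5, gender="f", ethnicity="Black")
        assert bset.select_key(rec) == "Black"

    def test_unknown_ethnicity_falls_back_to_global(self, rng):
        bset = self.make_set(rng)
        rec = M.DemographicRecord("s", age=40, gender="f",
                                  ethnicity="Martian")
        assert bset.select_key(rec) == "global"

    def test_missing_fallback_rejected(self, rng):
        model = toy_model(rng)
        with pytest.raises(ValueError, match="fallback"):
            M.BespokeModelSet(rules=[], models={"a": model},
                              fallback_key="global")


class TestPersistence:
    def test_hdf5_round_trip_bit_exact(self, tmp_path, rng):
        model = toy_model(rng)
        p = tmp_path / "model.h5"
        save_model(model, p)
        back = load_model(p)
        np.testing.assert_array_equal(back.mean, model.mean)
        np.testing.assert_array_equal(back.basis, model.basis)
        np.testing.assert_array_equal(back.eigenvalues, model.eigenvalues)
        np.testing.assert_array_equal(back.trilist, model.trilist)
        assert back.kind == model.kind
        assert back.total_variance == model.total_variance
        assert back.n_training == model.n_training

    def test_nested_keys_for_bespoke_archives(self, tmp_path, rng):
        m = toy_model(rng)
        p = tmp_path / "bespoke.h5"
        save_model(m, p, key="Black", mode="w")
        save_model(m, p, key="Chinese", mode="a")
        back = load_model(p, key="Chinese")
        np.testing.assert_array_equal(back.basis, m.basis)
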