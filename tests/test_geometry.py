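"""Procrustes and PCA machinery against analytic cases and brute-force oracles."""
import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from lvtraj.geometry import (SS, SSS, centroid_size, displacement_magnitude, fit_pca,
                             gpa, opa_align, reconstruct_shape_at_score, PCModel)

SQUARE = np.array([[1.0, 1.0, 0.0], [1.0, -1.0, 0.0], [-1.0, 1.0, 0.0], [-1.0, -1.0, 0.0]])


class TestCentroidSize:
    def test_square_analytic(self):
        assert centroid_size(SQUARE) == pytest.approx(np.sqrt(8.0))

    def test_homogeneity_and_translation_invariance(self, rng):
        x = rng.normal(size=(17, 3))
        assert centroid_size(3.0 * x) == pytest.approx(3.0 * centroid_size(x))
        assert centroid_size(x + [5.0, -2.0, 9.0]) == pytest.approx(centroid_size(x))

    def test_degenerate_coincident_landmarks(self):
        assert centroid_size(np.ones((6, 3))) == 0.0

    def test_nonfinite_rejected(self):
        bad = SQUARE.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            centroid_size(bad)


class TestOPA:
    def test_self_alignment_is_identity(self, rng):
        x = rng.normal(size=(8, 3))
        res = opa_align(x, x)
        assert res.residual == pytest.approx(0.0, abs=1e-20)
        assert res.rotation == pytest.approx(np.eye(3), abs=1e-10)
        assert res.scale == 1.0

    def test_congruent_pair_residual_zero(self, rng):
        x = rng.normal(size=(9, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = x @ R.T + np.array([2.0, 3.0, 0.0])
        assert opa_align(moved, x).residual == pytest.approx(0.0, abs=1e-18)

    def test_ss_mode_congruence_with_scaling(self, rng):
        x = rng.normal(size=(9, 3))
        moved = 2.5 * x @ Rotation.from_euler("xyz", [0.4, -0.2, 1.0]).as_matrix().T + 7.0
        res = opa_align(moved, x, mode=SS)
        # both are scaled to the source's size, so residual is zero after rotation
        assert res.residual == pytest.approx(0.0, abs=1e-18)

    def test_mirrored_shape_matches_brute_force_oracle(self, rng):
        """det=+1 constraint: the minimum over proper rotations, found by grid search
        plus refinement, must coincide with the closed-form solution."""
        x = rng.normal(size=(5, 3))
        mirrored = x * np.array([1.0, 1.0, -1.0])
        res = opa_align(mirrored, x)
        assert res.residual > 1e-2
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

        xc = x - x.mean(0)
        mc = mirrored - mirrored.mean(0)

        def residual(euler):
            R = Rotation.from_euler("xyz", euler).as_matrix()
            return np.sum((mc @ R - xc) ** 2)

        grid = np.linspace(-np.pi, np.pi, 13)
        best = min(((residual((a, b, c)), (a, b, c))
                    for a in grid for b in grid / 2 for c in grid), key=lambda t: t[0])
        refined = minimize(residual, best[1], method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        assert res.residual == pytest.approx(refined.fun, abs=1e-6)

    def test_residual_invariant_under_common_motion(self, rng):
        x = rng.normal(size=(10, 3))
        y = x + 0.3 * rng.normal(size=(10, 3))
        base = opa_align(x, y).residual
        R = Rotation.from_euler("xyz", rng.uniform(-np.pi, np.pi, 3)).as_matrix()
        moved = opa_align(x @ R.T + 4.0, y @ R.T + 4.0).residual
        assert moved == pytest.approx(base, abs=1e-8)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            opa_align(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))

    def test_degenerate_source_rejected(self, rng):
        with pytest.raises(ValueError):
            opa_align(rng.normal(size=(5, 3)), np.ones((5, 3)))


def _gpa_oracle(configs, scale, tol=1e-12, max_iter=500):
    """Straightforward independent GPA: explicit per-config SVD loop."""
    X = [c - c.mean(0) for c in configs]
    if scale:
        X = [c / np.sqrt((c * c).sum()) for c in X]
    ref = np.mean(X, axis=0)
    prev = np.inf
    for _ in range(max_iter):
        if scale:
            ref = ref / np.sqrt((ref * ref).sum())
        new = []
        for c in X:
            U, s, Vt = np.linalg.svd(c.T @ ref)
            d = np.sign(np.linalg.det(U @ Vt))
            R = (U * [1.0, 1.0, d]) @ Vt
            new.append(c @ R)
        X = new
        ref = np.mean(X, axis=0)
        obj = float(sum(np.sum((c - ref) ** 2) for c in X))
        if prev - obj <= tol * max(prev, 1e-30):
            break
        prev = obj
    return obj


class TestGPA:
    def test_identical_configurations_zero_objective(self, rng):
        x = rng.normal(size=(7, 3))
        res = gpa(np.stack([x, x]))
        assert res.objective == pytest.approx(0.0, abs=1e-20)
        assert res.consensus == pytest.approx(x - x.mean(0), abs=1e-12)

    @pytest.mark.parametrize("mode", [SSS, SS])
    def test_congruent_set_zero_objective(self, rng, mode):
        x = rng.normal(size=(8, 3))
        copies = []
        for i in range(3):
            R = Rotation.from_euler("xyz", rng.uniform(-2, 2, 3)).as_matrix()
            s = (1.0 + i) if mode == SS else 1.0
            copies.append(s * x @ R.T + rng.normal(size=3))
        res = gpa(np.stack(copies), mode=mode)
        assert res.objective == pytest.approx(0.0, abs=1e-16)

    @pytest.mark.parametrize("mode", [SSS, SS])
    def test_perturbed_sample_matches_independent_oracle(self, rng, mode):
        base = rng.normal(size=(10, 3))
        configs = np.stack([base + 0.1 * rng.normal(size=(10, 3)) for _ in range(10)])
        res = gpa(configs, mode=mode, tol=1e-14)
        oracle = _gpa_oracle(list(configs), scale=(mode == SS))
        assert res.objective == pytest.approx(oracle, abs=1e-6 * max(oracle, 1.0))
        assert res.objective <= res.objective_trace[0] + 1e-12

    def test_objective_trace_monotone(self, rng):
        configs = rng.normal(size=(12, 6, 3))
        res = gpa(configs)
        trace = np.array(res.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9 * trace[0])

    def test_consensus_is_mean_of_aligned(self, rng):
        configs = rng.normal(size=(5, 6, 3))
        res = gpa(configs)
        assert res.consensus == pytest.approx(res.aligned.mean(axis=0), abs=1e-12)
        # every aligned configuration is centered
        assert np.abs(res.aligned.mean(axis=1)).max() < 1e-10

    def test_ss_mode_unit_centroid_sizes(self, rng):
        configs = rng.normal(size=(6, 9, 3)) * 3.0
        res = gpa(configs, mode=SS)
        cs = np.sqrt((res.aligned ** 2).sum(axis=(1, 2)))
        assert cs == pytest.approx(np.ones(6), abs=1e-10)

    def test_sss_mode_preserves_centroid_sizes(self, rng):
        configs = rng.normal(size=(6, 9, 3)) * 3.0
        res = gpa(configs, mode=SSS)
        cs_in = [centroid_size(c) for c in configs]
        cs_out = [centroid_size(c) for c in res.aligned]
        assert cs_out == pytest.approx(cs_in, abs=1e-10)

    def test_rotations_are_proper(self, rng):
        configs = rng.normal(size=(5, 7, 3))
        res = gpa(configs)
        assert np.linalg.det(res.rotations) == pytest.approx(np.ones(5), abs=1e-10)


class TestPCA:
    def test_collinear_data_single_axis(self, rng):
        direction = rng.normal(size=12)
        X = np.outer(rng.normal(size=20), direction)
        model = fit_pca(X)
        assert model.explained_fraction[0] == pytest.approx(1.0)

    def test_reconstruction_completeness(self, rng):
        X = rng.normal(size=(20, 12))
        model = fit_pca(X)
        scores = model.transform(X)
        assert model.inverse_transform(scores) == pytest.approx(X, abs=1e-8)

    def test_score_variances_match_model(self, rng):
        X = rng.normal(size=(30, 8))
        model = fit_pca(X)
        scores = model.transform(X)
        assert scores.mean(axis=0) == pytest.approx(np.zeros(8), abs=1e-10)
        assert np.var(scores, axis=0, ddof=1) == pytest.approx(model.variances, abs=1e-8)

    def test_components_orthonormal_variances_sorted(self, rng):
        X = rng.normal(size=(15, 9))
        model = fit_pca(X)
        gram = model.components @ model.components.T
        assert gram == pytest.approx(np.eye(len(gram)), abs=1e-8)
        assert np.all(np.diff(model.variances) <= 1e-12)
        nonzero = model.explained_fraction[model.variances > 1e-12]
        assert model.explained_fraction.sum() == pytest.approx(1.0, abs=1e-10)

    def test_single_row_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(1, 5)))


class TestReconstructAtScore:
    def test_zero_score_gives_mean(self, rng):
        model = fit_pca(rng.normal(size=(10, 9)))
        assert reconstruct_shape_at_score(model, 0, 0.0).ravel() == \
            pytest.approx(model.mean_vector)

    def test_symmetry_about_mean(self, rng):
        model = fit_pca(rng.normal(size=(10, 9)))
        plus = reconstruct_shape_at_score(model, 1, 2.0)
        minus = reconstruct_shape_at_score(model, 1, -2.0)
        assert (plus + minus) / 2.0 == pytest.approx(model.mean_vector.reshape(-1, 3),
                                                     abs=1e-12)

    def test_full_score_vector_recovers_case(self, rng):
        """PCA completeness on a 10-case synthetic set: all-axis reconstruction
        returns the case's own configuration."""
        X = rng.normal(size=(10, 15))
        model = fit_pca(X)
        scores = model.transform(X)
        rec = model.mean_vector + scores[3] @ model.components
        assert rec == pytest.approx(X[3], abs=1e-8)

    def test_axis_out_of_range(self, rng):
        model = fit_pca(rng.normal(size=(5, 6)))
        with pytest.raises(IndexError):
            reconstruct_shape_at_score(model, 99, 1.0)


class TestDisplacementMagnitude:
    def test_identical_and_offset(self, rng):
        a = rng.normal(size=(6, 3))
        assert displacement_magnitude(a, a) == pytest.approx(np.zeros(6))
        assert displacement_magnitude(a, a + [0, 0, 1.0]) == pytest.approx(np.ones(6))

    def test_matches_naive_loop(self, rng):
        a, b = rng.normal(size=(2, 11, 3))
        naive = np.array([np.sqrt(((b[i] - a[i]) ** 2).sum()) for i in range(11)])
        assert displacement_magnitude(a, b) == pytest.approx(naive)

    def test_mismatched_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            displacement_magnitude(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))
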