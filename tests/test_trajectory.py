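"""Trajectory attributes and their group tests."""
import numpy as np
import pytest
from scipy import stats

from lvtraj.trajectory import (anova_adjusted, attribute_table, circular_variance,
                               dispersion_test, per_time_tests, trajectories,
                               trajectory_angle, trajectory_shape_analysis,
                               trajectory_size, wilks_manova)


def _circle_traj(radius=1.0, n=30, phase=0.0, ratio=1.0):
    t = 2 * np.pi * np.arange(n) / n + phase
    return np.column_stack([radius * np.cos(t), ratio * radius * np.sin(t),
                            np.zeros(n)])


class TestTrajectorySize:
    def test_degenerate_and_homogeneity(self, rng):
        pts = rng.normal(size=(30, 3))
        assert trajectory_size(np.zeros((30, 3))) == 0.0
        assert trajectory_size(2.0 * pts) == pytest.approx(2.0 * trajectory_size(pts))

    def test_circle_analytic(self):
        traj = _circle_traj(radius=2.5)
        assert trajectory_size(traj) == pytest.approx(2.5 * np.sqrt(30.0), abs=1e-9)

    def test_translation_invariance(self, rng):
        pts = rng.normal(size=(30, 3))
        assert trajectory_size(pts + [4.0, -1.0, 2.0]) == pytest.approx(
            trajectory_size(pts), abs=1e-9)


class TestTrajectoryAngle:
    def _traj_with_es(self, es_vec, plane="12", es_index=11):
        pts = np.zeros((30, 3))
        i, j = {"12": (0, 1), "13": (0, 2)}[plane]
        pts[es_index - 1, i] = es_vec[0]
        pts[es_index - 1, j] = es_vec[1]
        return pts

    def test_quadrant_examples(self):
        assert trajectory_angle(self._traj_with_es((1, 1))) == pytest.approx(45.0)
        assert trajectory_angle(self._traj_with_es((-1, 0))) == pytest.approx(180.0)
        assert trajectory_angle(self._traj_with_es((0, -1), plane="13"),
                                plane="13") == pytest.approx(270.0)

    def test_in_plane_rotation_equivariance(self, rng):
        pts = rng.normal(size=(30, 3))
        base = trajectory_angle(pts)
        theta = np.deg2rad(30.0)
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        rotated = pts @ R.T
        assert trajectory_angle(rotated) == pytest.approx((base + 30.0) % 360.0, abs=1e-9)

    def test_translation_invariance(self, rng):
        pts = rng.normal(size=(30, 3))
        assert trajectory_angle(pts + 5.0) == pytest.approx(trajectory_angle(pts))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            trajectory_angle(np.zeros((30, 3)))

    def test_circular_variance_range(self, rng):
        assert circular_variance([10.0] * 5) == pytest.approx(0.0, abs=1e-12)
        assert 0.0 <= circular_variance(rng.uniform(0, 360, 50)) <= 1.0


class TestAnovaAdjusted:
    def test_hand_computed_example(self):
        res = anova_adjusted([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.extra["r_squared"] == pytest.approx(13.5 / 17.5, abs=1e-6)
        assert res.r_squared_adj == pytest.approx(1 - (1 - 13.5 / 17.5) * 5 / 4, abs=1e-6)

    def test_identical_groups_null(self):
        res = anova_adjusted([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.r_squared_adj <= 0.0

    def test_degenerate_no_variance(self):
        res = anova_adjusted([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res.p_value == 1.0

    def test_matches_scipy_f_oneway(self, rng):
        for _ in range(100):
            a = rng.normal(size=rng.integers(3, 10))
            b = rng.normal(loc=rng.normal(), size=rng.integers(3, 10))
            res = anova_adjusted(np.concatenate([a, b]),
                                 ["a"] * len(a) + ["b"] * len(b))
            ref = stats.f_oneway(a, b)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_null_p_values_uniform(self, rng):
        """p-values under an exchangeable null are uniform (KS over 1,000 replicates)."""
        ps = []
        for _ in range(1000):
            x = rng.normal(size=20)
            ps.append(anova_adjusted(x, ["a"] * 10 + ["b"] * 10).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestWilksManova:
    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.multivariate.manova import MANOVA
        X = rng.normal(size=(40, 4))
        groups = np.array(["a"] * 20 + ["b"] * 20)
        X[20:] += [0.5, 0.0, -0.3, 0.1]
        res = wilks_manova(X, groups)
        exog = np.column_stack([np.ones(40), (groups == "b").astype(float)])
        sm = MANOVA(X, exog).mv_test().results["x1"]["stat"]
        assert res.extra["wilks_lambda"] == pytest.approx(
            float(sm.loc["Wilks' lambda", "Value"]), abs=1e-8)
        assert res.statistic == pytest.approx(float(sm.loc["Wilks' lambda", "F Value"]),
                                              rel=1e-6)
        assert res.p_value == pytest.approx(float(sm.loc["Wilks' lambda", "Pr > F"]),
                                            abs=1e-8)

    def test_strong_effect_small_lambda(self, rng):
        X = rng.normal(size=(30, 3)) * 0.01
        X[15:] += 5.0
        res = wilks_manova(X, ["a"] * 15 + ["b"] * 15)
        assert res.extra["wilks_lambda"] < 1e-3
        assert res.p_value < 1e-10


class TestTrajectoryShapeAnalysis:
    def test_rotated_scaled_copies_align_to_null(self, rng):
        """Groups differing only by in-plane rotation and scale coincide after
        shape-space GPA: Wilks' lambda ~ 1, p ~ 1."""
        trajs = []
        groups = []
        for g, (phase, scale) in (("a", (0.0, 1.0)), ("b", (np.pi / 6, 2.0))):
            for i in range(6):
                trajs.append(scale * _circle_traj(phase=phase))
                groups.append(g)
        scores, model, test = trajectory_shape_analysis(np.stack(trajs), groups)
        assert scores.shape[1] == 0 or np.abs(scores).max() < 1e-8
        assert test.extra["wilks_lambda"] == pytest.approx(1.0)
        assert test.p_value == pytest.approx(1.0)

    def test_circle_vs_ellipse_perfectly_separated(self, rng):
        trajs = []
        groups = []
        for i in range(8):
            trajs.append(_circle_traj() + 1e-6 * rng.normal(size=(30, 3)))
            groups.append("circle")
        for i in range(8):
            trajs.append(_circle_traj(ratio=0.5) + 1e-6 * rng.normal(size=(30, 3)))
            groups.append("ellipse")
        _, _, test = trajectory_shape_analysis(np.stack(trajs), groups, n_pcs=5)
        assert test.extra["wilks_lambda"] < 1e-3
        assert test.p_value < 1e-6

    def test_invariance_under_common_rotation_and_scale(self, rng):
        trajs = np.stack([_circle_traj(ratio=r) + 0.05 * rng.normal(size=(30, 3))
                          for r in np.linspace(0.5, 1.5, 12)])
        groups = ["a"] * 6 + ["b"] * 6
        _, _, t0 = trajectory_shape_analysis(trajs, groups, n_pcs=5)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        _, _, t1 = trajectory_shape_analysis(3.0 * trajs @ R.T, groups, n_pcs=5)
        assert t1.extra["wilks_lambda"] == pytest.approx(t0.extra["wilks_lambda"],
                                                         abs=1e-8)

    def test_explained_fractions_non_increasing(self, rng):
        trajs = rng.normal(size=(10, 30, 3))
        _, model, _ = trajectory_shape_analysis(trajs, ["a"] * 5 + ["b"] * 5, n_pcs=5)
        assert np.all(np.diff(model.explained_fraction) <= 1e-12)


class TestDispersionTest:
    def test_constructed_dispersion_effect_detected(self, rng):
        a = rng.normal(size=(15, 4))
        b = rng.normal(size=(15, 4)) * 3.0
        res = dispersion_test(np.vstack([a, b]), ["a"] * 15 + ["b"] * 15,
                              n_perm=499, seed=0)
        assert res.p_value < 0.01

    def test_null_is_calibrated(self, rng):
        """Same spherical cloud for both groups: rejection rate ~ alpha."""
        rejections = 0
        n_rep = 300
        for i in range(n_rep):
            X = rng.normal(size=(20, 3))
            res = dispersion_test(X, ["a"] * 10 + ["b"] * 10, n_perm=99, seed=i)
            rejections += res.p_value <= 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            dispersion_test(rng.normal(size=(10, 2)), ["a"] * 5 + ["b"] * 5, n_perm=0)

    def test_tiny_group_rejected(self, rng):
        with pytest.raises(ValueError):
            dispersion_test(rng.normal(size=(4, 2)), ["a", "a", "b", "b"])


class TestPerTimeTests:
    def test_table_structure_and_axis_bounds(self, transported_small):
        table = per_time_tests(transported_small, axis=0)
        assert len(table) == transported_small.n_frames
        assert {"F", "p", "r_squared_adj", "p_bh", "significant_bh"} <= set(table.columns)
        with pytest.raises(IndexError):
            per_time_tests(transported_small, axis=999)

    def test_effect_present_at_es_vanishes_at_mean_crossing(self, transported_small):
        """With the grand mean as transport target even ED is a deformed state, so
        amplitude-contrast groups differ at both ED and ES; the difference collapses
        only where the activation crosses its cycle mean (between ES and late
        diastole), and the ES frame itself stays strongly significant."""
        table = per_time_tests(transported_small, axis=0)
        crossing = table.loc[15:25, "F"].idxmin()
        assert table.loc[11, "F"] > 2.0 * table.loc[crossing, "F"]
        assert bool(table.loc[11, "significant_bh"])


class TestAttributeTable:
    def test_per_case_rows_and_columns(self, transported_small):
        table = attribute_table(transported_small)
        assert len(table) == transported_small.n_cases
        assert {"case_id", "group", "traj_size", "angle_12", "angle_13"} <= set(table.columns)
        assert table["traj_size"].min() > 0
        assert table.filter(like="shape_pc").shape[1] > 0
        ok = table[["angle_12", "angle_13"]].dropna()
        assert ((ok >= 0) & (ok < 360)).all().all()
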