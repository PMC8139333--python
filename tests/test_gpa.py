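"""Radial pseudolandmarks, GPA, permutation ANOVA and shape PCA."""

import numpy as np
import pytest

from fruitmorph import gpa
from conftest import ray_polygon, ellipse_radius
from _oracles import pairwise_procrustes


def rot(points, phi):
    M = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    return points @ M.T


class TestRadialLandmarks:
    def test_default_yields_fifty_points(self):
        poly = ray_polygon(lambda t: np.full_like(t, 3.0), 200)
        lm = gpa.radial_landmarks(poly)
        assert lm.points.shape == (50, 2)

    def test_circle_radii_exact(self):
        poly = ray_polygon(lambda t: np.full_like(t, 7.5), 200)
        lm = gpa.radial_landmarks(poly, k=50)
        assert np.allclose(np.hypot(*lm.points.T), 7.5, atol=1e-9)

    def test_ellipse_matches_polar_radius_law(self):
        r = ellipse_radius(2.0, 1.0)
        poly = ray_polygon(r, 200)
        lm = gpa.radial_landmarks(poly, k=50)
        expected = r(np.arange(50) * 2 * np.pi / 50)
        assert np.allclose(np.hypot(*lm.points.T), expected, atol=1e-9)

    def test_rotation_equivariance_with_shifted_start_angle(self):
        rng = np.random.default_rng(0)
        base_r = lambda t: 3.0 + 0.3 * np.cos(2 * t) + 0.2 * np.sin(3 * t)
        poly = ray_polygon(base_r, 300)
        phi = 0.37
        lm0 = gpa.radial_landmarks(poly, k=50)
        # rotation by phi in the (row, col) plane consistent with the ray convention
        rotated = np.column_stack(
            [
                np.cos(phi) * poly[:, 0] - np.sin(phi) * poly[:, 1],
                np.sin(phi) * poly[:, 0] + np.cos(phi) * poly[:, 1],
            ]
        )
        lm1 = gpa.radial_landmarks(rotated, k=50, theta0=-phi)
        back = np.column_stack(
            [
                np.cos(phi) * lm1.points[:, 0] + np.sin(phi) * lm1.points[:, 1],
                -np.sin(phi) * lm1.points[:, 0] + np.cos(phi) * lm1.points[:, 1],
            ]
        )
        assert np.allclose(back, lm0.points, atol=1e-8)

    def test_centroid_outside_raises(self):
        # a thin "C" shaped polygon whose area centroid lies outside
        t = np.linspace(-0.4 * np.pi, 0.4 * np.pi, 60)
        outer = np.column_stack([np.sin(t) * 2, np.cos(t) * 2])
        inner = np.column_stack([np.sin(t[::-1]) * 1.8, np.cos(t[::-1]) * 1.8])
        poly = np.vstack([outer, inner])
        with pytest.raises(ValueError):
            gpa.radial_landmarks(poly, k=50)


class TestOrientContour:
    def test_major_axis_made_vertical(self):
        r = ellipse_radius(2.0, 1.0)
        poly = ray_polygon(r, 200)  # major axis horizontal (col semi-axis 2)
        oriented = gpa.orient_contour(poly)
        h = oriented[:, 0].max() - oriented[:, 0].min()
        w = oriented[:, 1].max() - oriented[:, 1].min()
        assert h > 1.9 * w


class TestGpaAlign:
    def test_similarity_copies_align_exactly(self):
        rng = np.random.default_rng(0)
        base = ray_polygon(ellipse_radius(2.0, 1.0), 200)
        base = gpa.radial_landmarks(base, k=30).points
        configs = []
        for _ in range(6):
            phi, s = rng.uniform(0, 2 * np.pi), rng.uniform(0.5, 2.0)
            configs.append(s * rot(base, phi) + rng.normal(0, 10, 2))
        res = gpa.gpa_align([gpa.LandmarkConfiguration(c) for c in configs])
        assert res.per_landmark_sd.max() < 1e-8
        spread = res.aligned - res.aligned[0]
        assert np.abs(spread).max() < 1e-8

    def test_two_shapes_match_closed_form_pairwise_oracle(self):
        rng = np.random.default_rng(1)
        a = ray_polygon(ellipse_radius(2.0, 1.0), 200)
        a = gpa.radial_landmarks(a, k=30).points
        b = a + rng.normal(0, 0.05, a.shape)
        b = 1.7 * rot(b, 0.8) + 5.0
        res = gpa.gpa_align([gpa.LandmarkConfiguration(a), gpa.LandmarkConfiguration(b)])
        _, _, d_oracle = pairwise_procrustes(a, b)
        d_ours = float(((res.aligned[0] - res.aligned[1]) ** 2).sum())
        assert d_ours == pytest.approx(d_oracle, rel=1e-6, abs=1e-12)

    def test_global_prerotation_leaves_sd_invariant(self):
        rng = np.random.default_rng(2)
        base = ray_polygon(ellipse_radius(1.5, 1.0), 200)
        base = gpa.radial_landmarks(base, k=30).points
        configs = [base + rng.normal(0, 0.05, base.shape) for _ in range(8)]
        res0 = gpa.gpa_align([gpa.LandmarkConfiguration(c) for c in configs])
        res1 = gpa.gpa_align(
            [gpa.LandmarkConfiguration(rot(c, np.pi / 6)) for c in configs]
        )
        assert np.allclose(res0.per_landmark_sd, res1.per_landmark_sd, atol=1e-9)
        # mean shapes agree up to one global rotation
        _, _, d = pairwise_procrustes(res0.mean_shape, res1.mean_shape)
        assert d < 1e-12

    def test_objective_non_increasing_per_iteration(self):
        rng = np.random.default_rng(3)
        base = ray_polygon(ellipse_radius(1.5, 1.0), 200)
        base = gpa.radial_landmarks(base, k=30).points
        configs = [rot(base, rng.uniform(0, 6)) + rng.normal(0, 0.1, base.shape) for _ in range(10)]
        res = gpa.gpa_align([gpa.LandmarkConfiguration(c) for c in configs])
        hist = np.array(res.objective_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_degenerate_configuration_rejected(self):
        flat = np.zeros((30, 2))
        with pytest.raises(ValueError):
            gpa.gpa_align([gpa.LandmarkConfiguration(flat), gpa.LandmarkConfiguration(flat)])


class TestVariableRegions:
    def test_identical_shapes_flag_nothing(self):
        base = ray_polygon(ellipse_radius(1.5, 1.0), 200)
        base = gpa.radial_landmarks(base, k=30).points
        res = gpa.gpa_align([gpa.LandmarkConfiguration(base.copy()) for _ in range(5)])
        assert not gpa.variable_regions(res).any()

    def test_only_jittered_arc_flagged(self):
        rng = np.random.default_rng(4)
        base = ray_polygon(lambda t: np.full_like(t, 2.0), 200)
        base = gpa.radial_landmarks(base, k=40).points
        jitter_idx = [0, 1, 2]
        configs = []
        for _ in range(30):
            c = base.copy()
            c[jitter_idx] += rng.normal(0, 0.15, (len(jitter_idx), 2))
            configs.append(c)
        res = gpa.gpa_align([gpa.LandmarkConfiguration(c) for c in configs])
        flags = gpa.variable_regions(res)
        assert set(np.nonzero(flags)[0]) == set(jitter_idx)

    def test_flags_invariant_to_dataset_duplication(self):
        rng = np.random.default_rng(5)
        base = ray_polygon(ellipse_radius(1.5, 1.0), 200)
        base = gpa.radial_landmarks(base, k=30).points
        configs = [base + rng.normal(0, 0.05, base.shape) for _ in range(6)]
        res1 = gpa.gpa_align([gpa.LandmarkConfiguration(c) for c in configs])
        res2 = gpa.gpa_align([gpa.LandmarkConfiguration(c) for c in configs + configs])
        assert np.array_equal(gpa.variable_regions(res1), gpa.variable_regions(res2))


class TestProcrustesAnova:
    def _two_families(self, n_per=8, sep=True, seed=0):
        rng = np.random.default_rng(seed)
        a = gpa.radial_landmarks(ray_polygon(ellipse_radius(2.0, 1.0), 200), k=30).points
        b = gpa.radial_landmarks(ray_polygon(ellipse_radius(1.0, 1.0), 200), k=30).points
        if not sep:
            b = a
        configs = [a + rng.normal(0, 0.02, a.shape) for _ in range(n_per)]
        configs += [b + rng.normal(0, 0.02, b.shape) for _ in range(n_per)]
        res = gpa.gpa_align([gpa.LandmarkConfiguration(c) for c in configs])
        return res, ["g1"] * n_per + ["g2"] * n_per

    def test_separated_families_reach_minimum_p(self):
        res, groups = self._two_families(sep=True)
        out = gpa.procrustes_anova(res, groups, n_perm=100, seed=0)
        assert out.p_value == pytest.approx(1 / 101)

    def test_p_values_on_achievable_grid(self):
        res, groups = self._two_families(sep=False, seed=1)
        out = gpa.procrustes_anova(res, groups, n_perm=100, seed=1)
        grid = np.arange(1, 102) / 101
        assert np.min(np.abs(grid - out.p_value)) < 1e-12

    def test_label_permutation_leaves_null_distribution_unchanged(self):
        res, groups = self._two_families(sep=False, seed=2)
        out1 = gpa.procrustes_anova(res, groups, n_perm=100, seed=3)
        swapped = [{"g1": "g2", "g2": "g1"}[g] for g in groups]
        out2 = gpa.procrustes_anova(res, swapped, n_perm=100, seed=3)
        assert out1.observed_stat == pytest.approx(out2.observed_stat)
        assert out1.p_value == out2.p_value

    def test_single_group_rejected(self):
        res, groups = self._two_families(sep=False)
        with pytest.raises(ValueError):
            gpa.procrustes_anova(res, ["g"] * len(groups))


class TestShapePca:
    def test_one_dimensional_gradient_captured_by_pc1(self):
        a = gpa.radial_landmarks(ray_polygon(ellipse_radius(2.0, 1.0), 200), k=30).points
        b = gpa.radial_landmarks(ray_polygon(ellipse_radius(1.0, 1.0), 200), k=30).points
        configs = [(1 - w) * a + w * b for w in np.linspace(0, 1, 12)]
        res = gpa.gpa_align([gpa.LandmarkConfiguration(c) for c in configs])
        _, _, frac = gpa.shape_pca(res)
        assert frac[0] >= 0.99

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(6)
        base = gpa.radial_landmarks(ray_polygon(ellipse_radius(1.5, 1.0), 200), k=30).points
        configs = [base + rng.normal(0, 0.05, base.shape) for _ in range(10)]
        res = gpa.gpa_align([gpa.LandmarkConfiguration(c) for c in configs])
        _, _, frac = gpa.shape_pca(res)
        assert frac.sum() == pytest.approx(1.0, abs=1e-10)

    def test_scores_invariant_to_global_rotation_before_gpa(self):
        rng = np.random.default_rng(7)
        base = gpa.radial_landmarks(ray_polygon(ellipse_radius(1.5, 1.0), 200), k=30).points
        configs = [base + rng.normal(0, 0.05, base.shape) for _ in range(10)]
        res0 = gpa.gpa_align([gpa.LandmarkConfiguration(c) for c in configs])
        res1 = gpa.gpa_align([gpa.LandmarkConfiguration(rot(c, 0.5)) for c in configs])
        s0, _, _ = gpa.shape_pca(res0)
        s1, _, _ = gpa.shape_pca(res1)
        # scores match up to per-component sign
        for j in range(3):
            assert np.allclose(s0[:, j], s1[:, j], atol=1e-6) or np.allclose(
                s0[:, j], -s1[:, j], atol=1e-6
            )
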