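import numpy as np
import pytest

from streetseg import (
    align_to_trunk_axis,
    detect_undersegmentation,
    find_boundary_voxel,
    fit_circle_lsq,
    locate_trees,
    slice_breast_height,
    split_cluster,
)
from streetseg.core_io import Cluster, PointCloud
from streetseg.localization_split import CircleFit, CircleFitError

from conftest import cluster_from


def circle_points(a, b, r, n=200, rng=None, radial_sigma=0.0):
    rng = rng or np.random.default_rng(0)
    th = rng.uniform(0, 2 * np.pi, n)
    rr = r + rng.normal(0, radial_sigma, n) if radial_sigma else r
    return np.column_stack([a + rr * np.cos(th), b + rr * np.sin(th)])


class TestSliceBreastHeight:
    def test_cylinder_slab_fraction(self, rng):
        n = 2000
        pts = np.column_stack([0.1 * np.cos(rng.uniform(0, 7, n)),
                               0.1 * np.sin(rng.uniform(0, 7, n)),
                               rng.uniform(0, 2, n)])
        xy = slice_breast_height(cluster_from(pts))
        frac = len(xy) / n
        assert 0.03 <= frac <= 0.07  # 0.1 m window of a 2 m extent
        z = pts[:, 2] - pts[:, 2].min()
        assert len(xy) == ((z >= 1.25) & (z <= 1.35)).sum()

    def test_short_cluster_empty_slab(self, rng):
        pts = rng.uniform(0, 1.0, (100, 3))
        assert len(slice_breast_height(cluster_from(pts))) == 0

    def test_two_trunk_cluster_two_annuli(self, rng):
        t1 = np.column_stack([circle_points(0, 0, 0.1, 500, rng),
                              rng.uniform(0, 3, 500)])
        t2 = np.column_stack([circle_points(4, 0, 0.1, 500, rng),
                              rng.uniform(0, 3, 500)])
        xy = slice_breast_height(cluster_from(np.vstack([t1, t2])))
        assert (xy[:, 0] < 2).any() and (xy[:, 0] > 2).any()


class TestCircleFit:
    def test_symmetric_four_points_exact(self):
        fit = fit_circle_lsq([(1, 0), (0, 1), (-1, 0), (0, -1)])
        assert fit.a == pytest.approx(0, abs=1e-12)
        assert fit.b == pytest.approx(0, abs=1e-12)
        assert fit.r == pytest.approx(1, abs=1e-12)

    def test_circumcircle_of_three_points(self):
        fit = fit_circle_lsq([(0, 0), (2, 0), (1, 1)])
        assert (fit.a, fit.b) == (pytest.approx(1), pytest.approx(0.0, abs=1e-9))
        assert fit.r == pytest.approx(1)
        for p in [(0, 0), (2, 0), (1, 1)]:
            assert np.hypot(p[0] - fit.a, p[1] - fit.b) == pytest.approx(1)

    def test_noiseless_sample_machine_precision(self, rng):
        pts = circle_points(3, -2, 0.15, 500, rng)
        fit = fit_circle_lsq(pts)
        assert fit.a == pytest.approx(3, abs=1e-10)
        assert fit.b == pytest.approx(-2, abs=1e-10)
        assert fit.r == pytest.approx(0.15, abs=1e-10)
        assert fit.rms_residual <= 1e-9

    def test_noisy_radius_recovery(self):
        rng = np.random.default_rng(7)
        pts = circle_points(3, -2, 0.15, 200, rng, radial_sigma=0.005)
        fit = fit_circle_lsq(pts)
        assert abs(fit.r - 0.15) <= 0.01

    def test_translation_rotation_equivariance(self, rng):
        pts = circle_points(0.5, 0.2, 0.4, 100, rng, radial_sigma=0.01)
        base = fit_circle_lsq(pts)
        shift = fit_circle_lsq(pts + [10, -7])
        assert shift.a == pytest.approx(base.a + 10, abs=1e-9)
        assert shift.b == pytest.approx(base.b - 7, abs=1e-9)
        assert shift.r == pytest.approx(base.r, abs=1e-9)
        th = 0.73
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rot = fit_circle_lsq(pts @ R.T)
        np.testing.assert_allclose(R @ [base.a, base.b], [rot.a, rot.b],
                                   atol=1e-9)
        assert rot.r == pytest.approx(base.r, abs=1e-9)

    def test_collinear_raises(self):
        with pytest.raises(CircleFitError):
            fit_circle_lsq([(0, 0), (1, 1), (2, 2), (3, 3)])

    def test_too_few_points_raises(self):
        with pytest.raises(CircleFitError):
            fit_circle_lsq([(0, 0), (1, 0)])


def _trunked_tree(rng, center, trunk_r=0.12, height=8.0, crown_r=2.0,
                  crown_base=3.0, n_trunk=2000, n_crown=4000):
    th = rng.uniform(0, 2 * np.pi, n_trunk)
    trunk = np.column_stack([center[0] + trunk_r * np.cos(th),
                             center[1] + trunk_r * np.sin(th),
                             rng.uniform(0, crown_base, n_trunk)])
    v = rng.normal(size=(n_crown, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    ball = v * rng.uniform(0, 1, n_crown)[:, None] ** (1 / 3)
    c = (height - crown_base) / 2
    crown = np.column_stack([center[0] + ball[:, 0] * crown_r,
                             center[1] + ball[:, 1] * crown_r,
                             crown_base + c + ball[:, 2] * c])
    return np.vstack([trunk, crown])


class TestLocateTrees:
    def test_single_tree_single_fit(self, rng):
        pts = _trunked_tree(rng, (2.0, 3.0))
        located = locate_trees([cluster_from(pts)])
        cluster, fits = located[0]
        assert len(fits) == 1
        assert np.linalg.norm(fits[0].center - [2.0, 3.0]) <= 0.05
        assert not detect_undersegmentation(located[0])

    def test_two_trunk_cluster_two_fits(self, rng):
        pts = np.vstack([_trunked_tree(rng, (0, 0)),
                         _trunked_tree(rng, (4.0, 0))])
        located = locate_trees([cluster_from(pts)])
        _, fits = located[0]
        assert len(fits) == 2
        assert detect_undersegmentation(located[0])

    def test_crown_only_fragment_unlocatable(self, rng):
        pts = rng.uniform(0, 1, (300, 3)) + [0, 0, 5.0]
        pts = np.vstack([pts, pts + [0.2, 0, -4.9]])  # extent but no trunk ring
        located = locate_trees([cluster_from(rng.uniform(0, 0.5, (50, 3)))])
        _, fits = located[0]
        assert fits == []
        assert not detect_undersegmentation(located[0])


class TestAlignToTrunkAxis:
    def _fits(self, centers):
        return [CircleFit(a=x, b=y, r=0.1, rms_residual=0, n_points=10)
                for x, y in centers]

    def test_vertical_pair_rotates_to_u_axis(self, rng):
        pts = rng.uniform(-1, 7, (100, 3))
        cluster = cluster_from(pts)
        rotated, rec = align_to_trunk_axis(cluster, self._fits([(0, 0), (0, 6)]))
        np.testing.assert_allclose(rec["trunk_u"], [0, 6], atol=1e-12)
        # centers map onto the u axis
        c2 = (np.array([0, 6.0])[:, None] * [0, 1]).astype(float)
        rot_centers = (np.array([[0, 0], [0, 6.0]]) - rec["origin"]) @ rec["rotation"].T
        np.testing.assert_allclose(rot_centers[:, 1], 0, atol=1e-12)

    def test_3_4_5_triangle(self, rng):
        cluster = cluster_from(rng.uniform(0, 5, (50, 3)))
        rotated, rec = align_to_trunk_axis(cluster, self._fits([(0, 0), (3, 4)]))
        np.testing.assert_allclose(rec["trunk_u"], [0, 5], atol=1e-12)

    def test_isometry(self, rng):
        pts = rng.uniform(0, 5, (80, 3))
        cluster = cluster_from(pts)
        rotated, _ = align_to_trunk_axis(cluster, self._fits([(1, 1), (4, 2)]))
        d_before = np.linalg.norm(pts[None, :, :2] - pts[:, None, :2], axis=2)
        d_after = np.linalg.norm(rotated[None] - rotated[:, None], axis=2)
        np.testing.assert_allclose(d_before, d_after, atol=1e-9)

    def test_coincident_centers_degenerate(self, rng):
        cluster = cluster_from(rng.uniform(0, 1, (10, 3)))
        with pytest.raises(ValueError):
            align_to_trunk_axis(cluster, self._fits([(1, 1), (1, 1)]))


def gaussian_mixture_1d(rng, centers, sigmas, ns):
    us = [rng.normal(c, s, n) for c, s, n in zip(centers, sigmas, ns)]
    u = np.concatenate(us)
    return np.column_stack([u, rng.uniform(0, 1, len(u))])


class TestBoundaryVoxel:
    def test_symmetric_mixture_boundary_at_midpoint(self):
        rng = np.random.default_rng(5)
        rot = gaussian_mixture_1d(rng, [0, 6], [1.5, 1.5], [5000, 5000])
        plan = find_boundary_voxel(rot, [0, 6], voxel_width=0.5)
        assert len(plan.boundaries) == 1
        assert abs(plan.boundaries[0] - 3.0) <= 0.5

    def test_asymmetric_mixture_matches_numeric_argmin(self):
        rng = np.random.default_rng(6)
        n1, n2, s1, s2 = 8000, 8000, 1.0, 2.0
        rot = gaussian_mixture_1d(rng, [0, 6], [s1, s2], [n1, n2])
        plan = find_boundary_voxel(rot, [0, 6], voxel_width=0.5)
        # numeric argmin of the analytic mixture density on (0, 6)
        grid = np.linspace(0.01, 5.99, 2000)
        dens = (n1 / s1 * np.exp(-0.5 * (grid / s1) ** 2)
                + n2 / s2 * np.exp(-0.5 * ((grid - 6) / s2) ** 2))
        u_star = grid[np.argmin(dens)]
        assert u_star < 3.0  # valley shifts toward the tighter crown
        assert abs(plan.boundaries[0] - u_star) <= 0.5

    def test_empty_gap_voxel_chosen(self, rng):
        left = np.column_stack([rng.uniform(-2, 1.9, 3000), np.zeros(3000)])
        right = np.column_stack([rng.uniform(4.1, 8, 3000), np.zeros(3000)])
        rot = np.vstack([left, right])
        plan = find_boundary_voxel(rot, [0, 6], voxel_width=0.5)
        b = plan.boundaries[0]
        assert 1.9 <= b <= 4.1  # inside the empty gap

    def test_too_close_trunks_fall_back_to_midpoint(self, rng):
        rot = np.column_stack([rng.uniform(0, 0.6, 200), np.zeros(200)])
        with pytest.warns(UserWarning):
            plan = find_boundary_voxel(rot, [0.1, 0.5], voxel_width=0.5)
        assert plan.boundaries[0] == pytest.approx(0.3)


class TestSplitCluster:
    def test_two_tree_split_conserves_and_separates(self, rng):
        a = _trunked_tree(rng, (0, 0))
        b = _trunked_tree(rng, (4.0, 0))
        labels = np.concatenate([np.zeros(len(a), int), np.ones(len(b), int)])
        cluster = cluster_from(np.vstack([a, b]), labels=labels)
        located = locate_trees([cluster])
        _, fits = located[0]
        rotated, rec = align_to_trunk_axis(cluster, fits)
        plan = find_boundary_voxel(rotated, rec["trunk_u"], 0.5)
        children = split_cluster(cluster, rotated, plan)
        assert len(children) == 2
        assert sum(len(c) for c in children) == len(cluster)
        # each child contains exactly one trunk fit center
        for child in children:
            inside = 0
            for f in fits:
                d = np.linalg.norm(child.xy - f.center, axis=1)
                if (d < 0.3).any():
                    inside += 1
            assert inside == 1

    def test_three_collinear_trunks_three_children(self, rng):
        trees = [_trunked_tree(rng, (x, 0)) for x in (0, 5.0, 10.0)]
        cluster = cluster_from(np.vstack(trees))
        located = locate_trees([cluster])
        _, fits = located[0]
        assert len(fits) == 3
        rotated, rec = align_to_trunk_axis(cluster, fits)
        plan = find_boundary_voxel(rotated, rec["trunk_u"], 0.5)
        assert len(plan.boundaries) == 2
        children = split_cluster(cluster, rotated, plan)
        assert len(children) == 3
        assert sum(len(c) for c in children) == len(cluster)
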