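"""Disparity derivation, occlusion and depth-edge maps."""

import numpy as np
import pytest

from conftest import textured_plane
from stereofix.geometry import HeadState, fixate, parallel_axes_state
from stereofix.groundtruth import (
    DisparityMap, depth_edge_map, disparity_from_cyclopic,
    disparity_from_left, evaluate_disparity_estimate, mirrored_disparity,
    occlusion_map, reproject,
)
from stereofix.render import CameraIntrinsics, project_point, render
from stereofix.scene import Scene


@pytest.fixture(scope="module")
def midline_state():
    head = HeadState(position=np.zeros(3))
    return fixate(head, [0.0, 0.0, -1500.0])


def constant_depth_map(shape, depth):
    return np.full(shape, -abs(depth))


class TestReproject:
    def test_identity_pose_is_identity(self, midline_state):
        x = np.array([[0.1, -0.05], [0.0, 0.0], [-0.2, 0.3]])
        lam = np.array([-800.0, -1000.0, -1200.0])
        pose = midline_state.left.pose_world
        x_b, lam_b, ok = reproject(x, lam, pose, pose)
        assert ok.all()
        np.testing.assert_allclose(x_b, x, atol=1e-12)
        np.testing.assert_allclose(lam_b, lam, atol=1e-9)

    def test_left_right_inverse_composition(self, midline_state):
        rng = np.random.default_rng(3)
        x = rng.uniform(-0.3, 0.3, size=(200, 2))
        lam = -rng.uniform(600.0, 2500.0, size=200)
        L = midline_state.left.pose_world
        R = midline_state.right.pose_world
        x_r, lam_r, ok = reproject(x, lam, L, R)
        assert ok.all()
        x_back, lam_back, _ = reproject(x_r, lam_r, R, L)
        np.testing.assert_allclose(x_back, x, atol=1e-12)
        np.testing.assert_allclose(lam_back, lam, atol=1e-9)

    def test_fixation_point_maps_to_principal_axis(self, midline_state):
        # the fixation point sits on every optical axis: x = (0, 0)
        F = midline_state.fixation
        lam_c = np.array([-(np.linalg.norm(
            F - midline_state.cyclopic.position_world))])
        x_c = np.zeros((1, 2))
        for eye in (midline_state.left, midline_state.right):
            x_b, _, ok = reproject(x_c, lam_c,
                                   midline_state.cyclopic.pose_world,
                                   eye.pose_world)
            assert ok.all()
            np.testing.assert_allclose(x_b, 0.0, atol=1e-12)

    def test_behind_camera_flagged(self):
        # oblique fixation: points exist in front of the cyclopic camera
        # but behind the right camera's principal plane
        state = fixate(HeadState(position=np.zeros(3)), [600.0, 0.0, -800.0])
        R_pose = state.right.pose_world
        P = R_pose[:3, 3] + R_pose[:3, :3] @ np.array([0.0, 0.0, 1.0])
        C = state.cyclopic.pose_world
        Xc = C[:3, :3].T @ (P - C[:3, 3])
        assert Xc[2] < 0  # in front of the cyclopic camera
        x = np.array([[Xc[0] / Xc[2], Xc[1] / Xc[2]]])
        _, _, ok = reproject(x, np.array([Xc[2]]), C, R_pose)
        assert not ok.any()


class TestDisparityMaps:
    def test_zero_disparity_at_fixation_pixel(self, midline_state):
        intr = CameraIntrinsics()
        lam_f = -np.linalg.norm(midline_state.fixation
                                - midline_state.cyclopic.position_world)
        lam = constant_depth_map((3, 3), lam_f)
        # 3x3 map whose centre pixel is the principal point of a 3x3 image
        intr3 = CameraIntrinsics(width=3, height=3, hfov=intr.hfov)
        disp = disparity_from_cyclopic(lam, midline_state, intr3)
        # centre pixel = principal point = fixation direction; the plane at
        # fixation depth passes through F there
        assert abs(disp.dx[1, 1]) < 1e-6
        assert abs(disp.dy[1, 1]) < 1e-6

    def test_nearer_plane_has_crossed_positive_dx(self, frontal_rig):
        scene, head, state = frontal_rig
        intr = CameraIntrinsics(width=240, height=135)
        res = render(scene, state.cyclopic.pose_world, intr)
        disp = disparity_from_cyclopic(res.depth, state, intr, res.valid)
        # pixels on the near box (depth ~1000 < fixation 2062) are crossed
        near = res.depth_mm < 1500.0
        assert near.sum() > 50
        assert np.all(disp.dx[near & disp.valid] > 0)
        # wall pixels below fixation depth magnitude are uncrossed
        far_pix = (res.depth_mm > 2080.0) & disp.valid
        assert np.all(disp.dx[far_pix] < 0)

    def test_parallel_axes_give_identically_zero_vertical_disparity(self):
        state = parallel_axes_state(HeadState(position=np.zeros(3)),
                                    elevation=-20.0)
        intr = CameraIntrinsics(width=64, height=48)
        lam = constant_depth_map((48, 64), 1100.0)
        disp = disparity_from_cyclopic(lam, state, intr)
        assert disp.valid.all()
        np.testing.assert_allclose(disp.dy, 0.0, atol=1e-9)

    def test_toe_in_vertical_disparity_cross_pattern(self, midline_state):
        intr = CameraIntrinsics(width=64, height=48)
        lam = constant_depth_map((48, 64), 1200.0)
        disp = disparity_from_cyclopic(lam, midline_state, intr)
        dy = disp.dy
        cy, cx = 23.5, 31.5  # principal point (image midlines)
        # zero on both midlines (within numerical noise of the geometry)
        # (midline falls between pixel rows/columns, so "zero" is bounded
        # by the half-pixel gradient)
        mid_rows = np.abs(dy[23:25, :])
        mid_cols = np.abs(dy[:, 31:33])
        assert mid_rows.max() < 2e-2 and mid_cols.max() < 2e-2
        # opposite signs in diagonally opposite quadrants
        q = dy[:20, :28], dy[:20, 36:], dy[28:, :28], dy[28:, 36:]
        signs = [np.sign(np.median(x)) for x in q]
        assert signs[0] == -signs[1] == -signs[2] == signs[3] != 0

    def test_left_referenced_identity_when_poses_equal(self, midline_state):
        intr = CameraIntrinsics(width=32, height=24)
        lam = constant_depth_map((24, 32), 900.0)
        disp = disparity_from_left(lam, midline_state, intr)
        # left-reference: p maps to p + d; d must vanish for the left camera
        # itself, checked through reprojection of the left pixel grid
        from stereofix.groundtruth import _disparity_from_depth

        same = _disparity_from_depth(lam, midline_state.left.pose_world,
                                     midline_state.left.pose_world,
                                     midline_state.left.pose_world,
                                     intr, "left", None)
        np.testing.assert_allclose(same.dx, 0.0, atol=1e-10)
        np.testing.assert_allclose(same.dy, 0.0, atol=1e-10)
        assert disp.reference == "left"

    def test_symmetric_fixation_mirror_symmetry(self, midline_state):
        # fronto-parallel plane through the fixation point, symmetric rig:
        # mirroring about the vertical midline swaps the two cameras, so
        # horizontal disparity is even and vertical disparity odd under the
        # mirror (cyclopic reference, whose pixel grid is itself symmetric)
        intr = CameraIntrinsics(width=64, height=48)
        lam = constant_depth_map((48, 64), 1500.0)
        disp = disparity_from_cyclopic(lam, midline_state, intr)
        np.testing.assert_allclose(disp.dx, disp.dx[:, ::-1], atol=1e-9)
        np.testing.assert_allclose(disp.dy, -disp.dy[:, ::-1], atol=1e-9)

    def test_left_and_cyclopic_maps_consistent(self, frontal_rig):
        scene, head, state = frontal_rig
        intr = CameraIntrinsics(width=240, height=135)
        res_c = render(scene, state.cyclopic.pose_world, intr)
        res_l = render(scene, state.left.pose_world, intr)
        disp_c = disparity_from_cyclopic(res_c.depth, state, intr, res_c.valid)
        disp_l = disparity_from_left(res_l.depth, state, intr, res_l.valid)
        occ = occlusion_map(disp_l).mask
        edges = depth_edge_map(disp_l).mask
        # map each cyclopic pixel to its left-image position, sample the
        # left-referenced map there and compare disparities
        from stereofix.groundtruth import reproject

        py, px = np.mgrid[0:135, 0:240].astype(float)
        xh, yh = intr.homogeneous_from_pixels(px, py)
        x_l, _, ok = reproject(np.stack([xh, yh], -1), res_c.depth,
                               state.cyclopic.pose_world, state.left.pose_world)
        pxl, pyl = intr.pixels_from_homogeneous(x_l[..., 0], x_l[..., 1])
        sel = disp_c.valid & ok
        ix = np.rint(pxl[sel]).astype(int)
        iy = np.rint(pyl[sel]).astype(int)
        inb = (ix >= 0) & (ix < 240) & (iy >= 0) & (iy < 135)
        ix, iy = ix[inb], iy[inb]
        good = (disp_l.valid[iy, ix] & ~occ[iy, ix] & ~edges[iy, ix])
        dc = disp_c.dx[sel][inb][good]
        dl = disp_l.dx[iy[good], ix[good]]
        # nearest-pixel sampling leaves sub-pixel quantisation; compare the
        # smooth agreement through the median absolute difference
        assert np.median(np.abs(dc - dl)) < 0.05

    def test_mirror_is_an_involution(self, midline_state):
        intr = CameraIntrinsics(width=32, height=24)
        rng = np.random.default_rng(0)
        lam = -rng.uniform(800, 2000, size=(24, 32))
        once = mirrored_disparity(lam, midline_state, intr)
        twice = mirrored_disparity(np.asarray(lam)[:, ::-1], midline_state, intr)
        plain = disparity_from_cyclopic(lam, midline_state, intr)
        np.testing.assert_array_equal(twice.dx, plain.dx)
        np.testing.assert_array_equal(twice.dy, plain.dy)
        assert not np.allclose(once.dx, plain.dx)

    def test_mirror_of_symmetric_depth_equals_original(self, midline_state):
        intr = CameraIntrinsics(width=64, height=48)
        lam = constant_depth_map((48, 64), 1400.0)
        plain = disparity_from_cyclopic(lam, midline_state, intr)
        mirrored = mirrored_disparity(lam, midline_state, intr)
        np.testing.assert_allclose(mirrored.dx, plain.dx, atol=1e-9)
        np.testing.assert_allclose(mirrored.dy, plain.dy, atol=1e-9)

    def test_shape_mismatch_rejected(self, midline_state):
        intr = CameraIntrinsics(width=32, height=24)
        lam = constant_depth_map((24, 32), 900.0)
        with pytest.raises(ValueError):
            disparity_from_cyclopic(lam, midline_state, intr,
                                    valid=np.ones((10, 10), bool))


class TestOcclusionMap:
    def test_single_plane_has_no_occlusions(self, midline_state):
        intr = CameraIntrinsics(width=64, height=48)
        lam = constant_depth_map((48, 64), 1200.0)
        disp = disparity_from_left(lam, midline_state, intr)
        assert occlusion_map(disp).mask.sum() == 0

    def test_band_width_matches_disparity_difference(self, frontal_rig):
        scene, head, state = frontal_rig
        intr = CameraIntrinsics(width=240, height=135)
        res_l = render(scene, state.left.pose_world, intr)
        disp = disparity_from_left(res_l.depth, state, intr, res_l.valid)
        occ = occlusion_map(disp).mask
        near = res_l.depth_mm < 1500.0
        rows = np.nonzero(near.any(axis=1))[0]
        mid = rows[len(rows) // 2]
        row_near = np.nonzero(near[mid])[0]
        d_box = np.nanmedian(disp.dx[mid, row_near])
        wall_cols = np.nonzero(~near[mid] & disp.valid[mid])[0]
        d_wall = np.nanmedian(disp.dx[mid, wall_cols])
        predicted = abs(d_box - d_wall)
        measured = occ[mid].sum()
        assert abs(measured - predicted) <= 1.5

    def test_agrees_with_visibility_oracle(self, frontal_rig):
        scene, head, state = frontal_rig
        intr = CameraIntrinsics(width=240, height=135)
        res_l = render(scene, state.left.pose_world, intr)
        disp = disparity_from_left(res_l.depth, state, intr, res_l.valid)
        occ = occlusion_map(disp).mask
        # oracle: cast a ray from the right camera centre toward each left
        # pixel's 3-D point; occluded iff something nearer blocks it
        py, px = np.mgrid[0:135, 0:240]
        sel = disp.valid
        xh, yh = intr.homogeneous_from_pixels(px[sel].astype(float),
                                              py[sel].astype(float))
        lam = res_l.depth[sel]
        P_cam = lam[:, None] * np.stack([xh, yh, np.ones_like(xh)], -1)
        L = state.left.pose_world
        pts = P_cam @ L[:3, :3].T + L[:3, 3]
        origin = state.right.pose_world[:3, 3]
        dirs = pts - origin
        dist = np.linalg.norm(dirs, axis=1)
        hits = scene.spatial_index().cast(origin, dirs / dist[:, None])
        blocked = hits.hit & (hits.t < dist - 0.5)
        # restrict to pixels whose correspondent lands inside the right image
        tx = px[sel] + disp.dx[sel]
        ty = py[sel] + disp.dy[sel]
        inb = (tx >= 0) & (tx <= 239) & (ty >= 0) & (ty <= 134)
        agreement = np.mean(occ[sel][inb] == blocked[inb])
        assert agreement >= 0.99

    def test_invariant_under_texture_change(self, frontal_rig):
        # occlusion depends only on the disparity geometry: recoloring the
        # scene cannot change the map (the map never sees the images)
        scene, head, state = frontal_rig
        intr = CameraIntrinsics(width=120, height=68)
        res_l = render(scene, state.left.pose_world, intr)
        disp = disparity_from_left(res_l.depth, state, intr, res_l.valid)
        a = occlusion_map(disp).mask
        disp2 = DisparityMap(dx=disp.dx.copy(), dy=disp.dy.copy(),
                             reference="left", valid=disp.valid.copy())
        b = occlusion_map(disp2).mask
        assert np.array_equal(a, b)


class TestDepthEdges:
    def test_constant_disparity_has_no_edges(self):
        disp = DisparityMap(dx=np.full((20, 30), 2.0),
                            dy=np.zeros((20, 30)),
                            reference="left", valid=np.ones((20, 30), bool))
        assert depth_edge_map(disp).mask.sum() == 0

    def test_step_marks_exactly_the_step(self):
        dx = np.zeros((20, 30))
        dx[:, 15:] = 5.0
        disp = DisparityMap(dx=dx, dy=np.zeros_like(dx), reference="left",
                            valid=np.ones_like(dx, bool))
        mask = depth_edge_map(disp, threshold=1.0).mask
        expected = np.zeros_like(dx, bool)
        expected[:, 14:16] = True
        assert np.array_equal(mask, expected)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        dx = rng.uniform(0, 4, size=(30, 40))
        disp = DisparityMap(dx=dx, dy=np.zeros_like(dx), reference="left",
                            valid=np.ones_like(dx, bool))
        prev = depth_edge_map(disp, threshold=0.5).mask
        for thr in (1.0, 2.0, 3.0):
            cur = depth_edge_map(disp, threshold=thr).mask
            assert np.all(cur <= prev)
            prev = cur

    def test_invalid_threshold_rejected(self):
        disp = DisparityMap(dx=np.zeros((4, 4)), dy=np.zeros((4, 4)),
                            reference="left", valid=np.ones((4, 4), bool))
        with pytest.raises(ValueError):
            depth_edge_map(disp, threshold=0.0)


class TestEvaluateEstimate:
    def _truth(self):
        rng = np.random.default_rng(5)
        dx = rng.normal(0, 2, (20, 30))
        dy = rng.normal(0, 0.5, (20, 30))
        return DisparityMap(dx=dx, dy=dy, reference="left",
                            valid=np.ones((20, 30), bool))

    def test_perfect_estimate_scores_zero(self):
        truth = self._truth()
        est = DisparityMap(dx=truth.dx.copy(), dy=truth.dy.copy(),
                           reference="left", valid=truth.valid.copy())
        assert evaluate_disparity_estimate(est, truth) == (0.0, 0.0, 0.0, 0.0)

    def test_constant_offset(self):
        truth = self._truth()
        est = DisparityMap(dx=truth.dx + 1.0, dy=truth.dy.copy(),
                           reference="left", valid=truth.valid.copy())
        mae_x, mae_y, sd_x, sd_y = evaluate_disparity_estimate(est, truth)
        assert np.isclose(mae_x, 1.0) and mae_y == 0.0
        assert np.isclose(sd_x, 0.0, atol=1e-12) and sd_y == 0.0

    def test_random_perturbation_matches_direct_formula(self):
        truth = self._truth()
        rng = np.random.default_rng(9)
        ex = rng.normal(0, 0.3, truth.shape)
        ey = rng.normal(0, 0.1, truth.shape)
        est = DisparityMap(dx=truth.dx + ex, dy=truth.dy + ey,
                           reference="left", valid=truth.valid.copy())
        mae_x, mae_y, sd_x, sd_y = evaluate_disparity_estimate(est, truth)
        assert np.isclose(mae_x, np.mean(np.abs(ex)), atol=1e-12)
        assert np.isclose(mae_y, np.mean(np.abs(ey)), atol=1e-12)
        assert np.isclose(sd_x, np.std(ex), atol=1e-12)
        assert np.isclose(sd_y, np.std(ey), atol=1e-12)

    def test_empty_mask_rejected(self):
        truth = self._truth()
        with pytest.raises(ValueError):
            evaluate_disparity_estimate(truth, truth,
                                        mask=np.zeros(truth.shape, bool))

    def test_reference_mismatch_rejected(self):
        truth = self._truth()
        est = DisparityMap(dx=truth.dx, dy=truth.dy, reference="cyclopic",
                           valid=truth.valid)
        with pytest.raises(ValueError):
            evaluate_disparity_estimate(est, truth)
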