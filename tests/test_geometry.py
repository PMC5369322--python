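"""Gimbal rotations, L2 torsion and the toe-in fixation construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stereofix.geometry import (
    DegenerateTargetError, HeadState, OutOfRangeError, REFERENCE_AXIS,
    elemental_rotation, eye_rotation, fick_angles, fixate, head_pose,
    head_rotation, helmholtz_angles, helmholtz_angles_to_target,
    invert_pose, l2_torsion, listing_plane_tilt, parallel_axes_state,
    quaternion_to_rotation, rotation_to_quaternion,
)

angles = st.floats(-80, 80)


def assert_rotation(R, tol=1e-12):
    assert np.allclose(R.T @ R, np.eye(3), atol=tol)
    assert np.isclose(np.linalg.det(R), 1.0, atol=tol)


class TestElementalRotations:
    def test_zero_angle_is_identity(self):
        for axis in "xyz":
            assert np.allclose(elemental_rotation(axis, 0.0), np.eye(3))

    def test_roll_by_90_sends_x_to_y(self):
        assert np.allclose(elemental_rotation("z", 90.0) @ [1, 0, 0],
                           [0, 1, 0], atol=1e-12)

    def test_inverse_rotation_cancels(self):
        R = elemental_rotation("y", 30.0) @ elemental_rotation("y", -30.0)
        assert np.allclose(R, np.eye(3), atol=1e-12)

    def test_nonfinite_angle_rejected(self):
        with pytest.raises(OutOfRangeError):
            elemental_rotation("x", np.nan)

    @given(axis=st.sampled_from("xyz"), angle=st.floats(-360, 360))
    @settings(deadline=None, derandomize=True)
    def test_always_orthonormal(self, axis, angle):
        assert_rotation(elemental_rotation(axis, angle))


class TestGimbals:
    def test_head_rotation_identity_and_single_axis(self):
        assert np.allclose(head_rotation(0, 0), np.eye(3))
        assert np.allclose(head_rotation(0, 30), elemental_rotation("y", 30))

    def test_head_rotation_composition_order(self):
        expected = elemental_rotation("y", 40) @ elemental_rotation("x", 20)
        assert np.allclose(head_rotation(20, 40), expected, atol=1e-14)

    def test_eye_rotation_composition_order(self):
        expected = elemental_rotation("x", 20) @ elemental_rotation("y", 40)
        assert np.allclose(eye_rotation(20, 40), expected, atol=1e-14)

    def test_fick_vs_helmholtz_differ_off_axis(self):
        assert not np.allclose(eye_rotation(20, 40), head_rotation(20, 40))
        assert np.allclose(eye_rotation(0, 25), head_rotation(0, 25))
        assert np.allclose(eye_rotation(25, 0), head_rotation(25, 0))

    @given(alpha=angles, beta=angles)
    @settings(deadline=None, derandomize=True)
    def test_head_rotation_has_zero_fick_torsion(self, alpha, beta):
        a, b, g = fick_angles(head_rotation(alpha, beta))
        assert abs(a - alpha) < 1e-9
        assert abs(b - beta) < 1e-9
        assert abs(g) < 1e-9

    @given(alpha=angles, beta=angles, gamma=st.floats(-30, 30))
    @settings(deadline=None, derandomize=True)
    def test_helmholtz_decomposition_roundtrip(self, alpha, beta, gamma):
        R = eye_rotation(alpha, beta) @ elemental_rotation("z", gamma)
        a, b, g = helmholtz_angles(R)
        assert np.allclose([a, b, g], [alpha, beta, gamma], atol=1e-9)


class TestHeadPose:
    def test_pure_translation(self):
        head = HeadState(position=[0, 0, 1550])
        P = head_pose(head)
        assert np.allclose(P[:3, :3], np.eye(3))
        assert np.allclose(P[:3, 3], [0, 0, 1550])

    def test_pose_maps_head_origin_to_world_position(self):
        head = HeadState(position=[10, 20, 30], elevation=-25, azimuth=40)
        P = head_pose(head)
        assert np.allclose(P @ [0, 0, 0, 1], [10, 20, 30, 1])

    def test_pose_inverse_roundtrip(self):
        head = HeadState(position=[5, -7, 1200], elevation=-30, azimuth=60)
        P = head_pose(head)
        assert np.allclose(P @ invert_pose(P), np.eye(4), atol=1e-10)


class TestHelmholtzAngles:
    def test_on_axis_target_gives_zero_angles(self):
        alpha, beta = helmholtz_angles_to_target([0, 0, 0], [0, 0, -500])
        assert alpha == 0.0 and beta == 0.0

    @given(x=st.floats(-800, 800), y=st.floats(-800, 800),
           z=st.floats(-2500, -200))
    @settings(deadline=None, derandomize=True)
    def test_forward_rotation_recovers_direction(self, x, y, z):
        target = np.array([x, y, z])
        alpha, beta = helmholtz_angles_to_target(np.zeros(3), target)
        gaze = eye_rotation(alpha, beta) @ REFERENCE_AXIS
        expected = target / np.linalg.norm(target)
        # sin of the angular error (well conditioned near zero)
        assert np.linalg.norm(np.cross(gaze, expected)) < 1e-9

    def test_convergent_signs_and_positive_vergence(self):
        # near midline target: left eye turns rightward (beta<0), right
        # eye leftward (beta>0) so that vergence = beta_R - beta_L > 0
        _, beta_l = helmholtz_angles_to_target([-30, 0, 0], [0, 0, -600])
        _, beta_r = helmholtz_angles_to_target([30, 0, 0], [0, 0, -600])
        assert beta_r > 0 > beta_l
        assert beta_r - beta_l > 0

    def test_degenerate_and_rear_targets_rejected(self):
        with pytest.raises(DegenerateTargetError):
            helmholtz_angles_to_target([1, 2, 3], [1, 2, 3])
        with pytest.raises(OutOfRangeError):
            helmholtz_angles_to_target([0, 0, 0], [0, 0, 500])


class TestListingTilt:
    def test_zero_vergence_gives_zero_tilt(self):
        assert listing_plane_tilt(0.0, 17.0, 0.8) == (0.0, 0.0)

    @given(nu=st.floats(-30, 30), xi=st.floats(-60, 60),
           delta=st.floats(0, 1))
    @settings(deadline=None, derandomize=True)
    def test_antisymmetry(self, nu, xi, delta):
        phi_l, phi_r = listing_plane_tilt(nu, xi, delta)
        assert phi_l == -phi_r

    def test_scalar_value(self):
        # (delta/2) * asin(sin(10 deg) / (2 cos 0)) at delta = 0.8
        phi_l, _ = listing_plane_tilt(10.0, 0.0, 0.8)
        expected = np.rad2deg(0.4 * np.arcsin(np.sin(np.deg2rad(10.0)) / 2.0))
        assert np.isclose(phi_l, expected, atol=1e-12)
        assert np.isclose(phi_l, 1.9927, atol=5e-4)


class TestTorsion:
    def test_zero_elevation_means_zero_torsion(self):
        for beta, phi in [(25.0, 2.0), (-40.0, 0.0), (0.0, 1.5)]:
            assert l2_torsion(0.0, beta, phi) == 0.0

    def test_zero_numerator(self):
        assert l2_torsion(20.0, 0.0, 0.0) == 0.0

    def test_scalar_value(self):
        # literal evaluation of the torsion formula at alpha=20, beta=15, phi=2
        gamma = l2_torsion(20.0, 15.0, 2.0)
        tphi, tbeta = np.tan(np.deg2rad(2.0)), np.tan(np.deg2rad(15.0))
        expected = np.rad2deg(2 * np.arctan(
            -np.tan(np.deg2rad(10.0)) * (tphi + tbeta) / (1 + tphi * tbeta)))
        assert np.isclose(gamma, expected, atol=1e-12)
        assert np.isclose(gamma, -6.0573, atol=5e-4)


class TestFixate:
    def test_symmetric_fixation_is_antisymmetric(self):
        head = HeadState(position=np.zeros(3))
        state = fixate(head, [0.0, 300.0, -900.0])
        assert np.isclose(state.left.beta, -state.right.beta, atol=1e-12)
        assert np.isclose(state.left.gamma, -state.right.gamma, atol=1e-12)
        assert np.isclose(state.version, 0.0, atol=1e-12)

    def test_vergence_matches_planar_trigonometry(self):
        head = HeadState(position=np.zeros(3))
        state = fixate(head, [0.0, 0.0, -1000.0], baseline=60.0)
        expected = np.rad2deg(2 * np.arctan(30.0 / 1000.0))
        assert np.isclose(state.vergence, expected, atol=1e-12)

    def test_vergence_version_consistent_with_stored_angles(self):
        head = HeadState(position=[100, 50, 800], elevation=-20, azimuth=25)
        state = fixate(head, [50, 100, -600])
        assert state.vergence == state.right.beta - state.left.beta
        assert state.version == 0.5 * (state.left.beta + state.right.beta)
        T = state.right.origin - state.left.origin
        assert np.isclose(np.linalg.norm(T), state.baseline)

    def test_mode_none_gives_pure_helmholtz(self):
        head = HeadState(position=np.zeros(3))
        state = fixate(head, [0.0, 200.0, -1200.0], listing_mode="none")
        for eye in (state.left, state.right):
            assert eye.gamma == 0.0
            assert np.allclose(eye.rotation, eye_rotation(eye.alpha, eye.beta))

    def test_mode_ll_zeroes_the_tilt_but_not_the_false_torsion(self):
        head = HeadState(position=np.zeros(3))
        state = fixate(head, [200.0, 300.0, -800.0], listing_mode="ll")
        assert state.left.phi == 0.0 == state.right.phi
        assert state.left.gamma != 0.0  # false torsion survives

    def test_cyclopic_carries_no_torsion(self):
        head = HeadState(position=[0, 100, 500], elevation=-35, azimuth=-15)
        state = fixate(head, [-100, 0, -700])
        assert state.cyclopic.gamma == 0.0

    @given(px=st.floats(-400, 400), py=st.floats(-300, 300),
           pz=st.floats(-2200, -500), el=st.floats(-45, 0),
           az=st.floats(-60, 60))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_both_axes_pass_through_fixation(self, px, py, pz, el, az):
        head = HeadState(position=[0, 800, 1500], elevation=el, azimuth=az)
        F = head.position + head.rotation @ np.array([px, py, pz])
        state = fixate(head, F)
        for eye in (state.left, state.right, state.cyclopic):
            d = F - eye.position_world
            d /= np.linalg.norm(d)
            assert np.linalg.norm(np.cross(d, eye.optical_axis_world)) < 1e-9

    def test_fixation_on_baseline_rejected(self):
        head = HeadState(position=np.zeros(3))
        with pytest.raises(DegenerateTargetError):
            fixate(head, [100.0, 0.0, 0.0])

    def test_parallel_axes_state_has_parallel_axes(self):
        state = parallel_axes_state(HeadState(position=np.zeros(3)),
                                    elevation=-10.0)
        assert np.allclose(state.left.optical_axis_world,
                           state.right.optical_axis_world)
        assert state.vergence == 0.0


class TestQuaternions:
    @given(alpha=angles, beta=angles, gamma=st.floats(-30, 30))
    @settings(deadline=None, derandomize=True)
    def test_roundtrip_and_unit_norm(self, alpha, beta, gamma):
        R = eye_rotation(alpha, beta) @ elemental_rotation("z", gamma)
        q = rotation_to_quaternion(R)
        assert np.isclose(np.linalg.norm(q), 1.0, atol=1e-12)
        assert q[0] >= 0  # canonical (w, x, y, z) sign
        assert np.allclose(quaternion_to_rotation(q), R, atol=1e-12)
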