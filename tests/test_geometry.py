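import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kappacal as kc
from kappacal.geometry import (
    AngularPose,
    GeometryError,
    GimbalLockError,
    angles_from_direction,
    build_eyeball_frame,
    direction_from_angles,
    direction_to_camera,
    direction_to_eyeball,
    ordered_corners,
    visual_axis_from_optical,
)

REMOTE_CORNERS = kc.remote_scene().screen_corners


def unit_vectors(draw_phi_margin=1e-3):
    """Strategy: unit vectors whose vertical component stays off the poles."""
    return st.tuples(
        st.floats(-180.0, 180.0),
        st.floats(-89.0, 89.0),
    ).map(lambda wp: direction_from_angles(AngularPose(*wp)))


class TestEyeballFrame:
    def test_axis_aligned_screen_gives_identity(self, flat_screen):
        frame = build_eyeball_frame(flat_screen, [0.0, 0.0, 500.0])
        np.testing.assert_allclose(frame.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(frame.origin, [0, 0, 500])

    def test_axis_aligned_screen_any_cycle_order(self):
        # corners listed starting from the bottom-left, still identity
        corners = [(-200, -100, 0), (200, -100, 0), (200, 100, 0), (-200, 100, 0)]
        frame = build_eyeball_frame(corners, [0.0, 0.0, 500.0])
        np.testing.assert_allclose(frame.rotation, np.eye(3), atol=1e-12)

    def test_remote_screen_frame_is_orthonormal_and_faces_eye(self):
        c = np.array([-30.0, -70.0, 500.0])
        frame = build_eyeball_frame(REMOTE_CORNERS, c)
        r = frame.rotation
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)
        center = REMOTE_CORNERS.mean(axis=0)
        assert np.dot(r[2], c - center) > 0  # z-axis points toward the eye

    def test_rotation_shared_between_eyes(self):
        left = build_eyeball_frame(REMOTE_CORNERS, [-33.6, -62.6, 508.7])
        right = build_eyeball_frame(REMOTE_CORNERS, [24.6, -76.5, 505.4])
        np.testing.assert_allclose(left.rotation, right.rotation, atol=1e-14)

    def test_coincident_corners_rejected(self):
        corners = [(0, 0, 0), (0, 0, 0), (1, 1, 0), (0, 1, 0)]
        with pytest.raises(GeometryError):
            build_eyeball_frame(corners, [0, 0, 500])

    def test_non_coplanar_corners_rejected(self):
        corners = [(-1, -1, 0), (1, -1, 0.5), (1, 1, 0), (-1, 1, 0)]
        with pytest.raises(GeometryError):
            build_eyeball_frame(corners, [0, 0, 500])

    def test_eye_on_screen_plane_rejected(self, flat_screen):
        with pytest.raises(GeometryError):
            build_eyeball_frame(flat_screen, [10.0, 10.0, 0.0])

    def test_rolled_screen_maps_camera_x_to_frame_y(self):
        # screen rolled by 90 deg: its horizontal edge runs along camera y
        corners = [(-100, -200, 0), (-100, 200, 0), (100, 200, 0), (100, -200, 0)]
        frame = build_eyeball_frame(corners, [0.0, 0.0, 500.0])
        mapped = frame.direction_to_eyeball([1.0, 0.0, 0.0])
        assert abs(mapped[0]) < 1e-12 and abs(mapped[2]) < 1e-12
        assert abs(abs(mapped[1]) - 1.0) < 1e-12

    def test_ordered_corners_fixes_crossed_input(self):
        # crossed order (TL, BR, TR, BL) is re-ordered into the cycle
        tl, tr, br, bl = ordered_corners(REMOTE_CORNERS[[0, 2, 1, 3]])
        np.testing.assert_allclose(tl, REMOTE_CORNERS[0])
        np.testing.assert_allclose(br, REMOTE_CORNERS[2])


class TestDirections:
    def test_identity_frame_passthrough(self, flat_screen):
        frame = build_eyeball_frame(flat_screen, [0, 0, 500])
        np.testing.assert_allclose(
            direction_to_eyeball(frame, [0, 0, -1]), [0, 0, -1], atol=1e-15
        )

    def test_round_trip_many_directions(self, remote_frame, rng):
        for _ in range(100):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            back = direction_to_camera(remote_frame, direction_to_eyeball(remote_frame, v))
            np.testing.assert_allclose(back, v, atol=1e-12)

    def test_non_unit_input_rejected(self, remote_frame):
        with pytest.raises(GeometryError):
            direction_to_eyeball(remote_frame, [0, 0, -2])


class TestAngularRepresentation:
    @pytest.mark.parametrize(
        "v, omega, phi",
        [
            ((0, 0, -1), 0.0, 0.0),
            ((1, 0, 0), 90.0, 0.0),
            ((-1, 0, 0), -90.0, 0.0),
        ],
    )
    def test_cardinal_directions(self, v, omega, phi):
        pose = angles_from_direction(np.array(v, dtype=float))
        assert pose.omega == pytest.approx(omega, abs=1e-12)
        assert pose.phi == pytest.approx(phi, abs=1e-12)

    def test_forward_inverse_at_30_10(self):
        # oracle: forward-evaluate the parameterisation at (30, 10) deg
        w, p = math.radians(30), math.radians(10)
        v = np.array(
            [math.cos(p) * math.sin(w), math.sin(p), -math.cos(p) * math.cos(w)]
        )
        np.testing.assert_allclose(v, [0.4924, 0.1736, -0.8529], atol=5e-5)
        pose = angles_from_direction(v)
        assert pose.omega == pytest.approx(30.0, abs=1e-3)
        assert pose.phi == pytest.approx(10.0, abs=1e-3)

    @pytest.mark.parametrize(
        "omega, phi, expected",
        [
            (0.0, 0.0, (0.0, 0.0, -1.0)),
            (90.0, 0.0, (1.0, 0.0, 0.0)),
            (5.0, 1.5, (0.087126, 0.026177, -0.995853)),
        ],
    )
    def test_direction_from_angles(self, omega, phi, expected):
        v = direction_from_angles(AngularPose(omega, phi))
        np.testing.assert_allclose(v, expected, atol=1e-5)
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-15)

    def test_vertical_direction_is_gimbal_locked(self):
        with pytest.raises(GimbalLockError):
            angles_from_direction(np.array([0.0, 1.0, 0.0]))

    @settings(max_examples=300, derandomize=True)
    @given(
        omega=st.floats(-179.9, 180.0),
        phi=st.floats(-89.99, 89.99),
    )
    def test_angle_round_trip_property(self, omega, phi):
        v = direction_from_angles(AngularPose(omega, phi))
        back = direction_from_angles(angles_from_direction(v))
        np.testing.assert_allclose(back, v, atol=1e-12)


class TestVisualAxisSynthesis:
    def test_zero_kappa_is_identity(self, remote_frame, rng):
        for _ in range(20):
            w, p = rng.uniform(-60, 60), rng.uniform(-45, 45)
            v = remote_frame.direction_to_camera(
                direction_from_angles(AngularPose(w, p))
            )
            np.testing.assert_allclose(
                visual_axis_from_optical(v, remote_frame, 0.0, 0.0), v, atol=1e-12
            )

    def test_angle_superposition_at_identity_frame(self, flat_screen):
        frame = build_eyeball_frame(flat_screen, [0, 0, 500])
        va = visual_axis_from_optical([0.0, 0.0, -1.0], frame, 5.0, 1.5)
        np.testing.assert_allclose(va, [0.087126, 0.026177, -0.995853], atol=1e-5)

    def test_unit_norm_preserved(self, remote_frame, rng):
        for _ in range(50):
            w, p = rng.uniform(-60, 60), rng.uniform(-40, 40)
            v = remote_frame.direction_to_camera(
                direction_from_angles(AngularPose(w, p))
            )
            va = visual_axis_from_optical(v, remote_frame, 5.0, 1.5)
            assert abs(np.linalg.norm(va) - 1.0) < 1e-12

    def test_kappa_inverse_restores_optical_axis(self, remote_frame, rng):
        for _ in range(50):
            w, p = rng.uniform(-60, 60), rng.uniform(-40, 40)
            oa = remote_frame.direction_to_camera(
                direction_from_angles(AngularPose(w, p))
            )
            va = visual_axis_from_optical(oa, remote_frame, 5.0, 1.5)
            back = visual_axis_from_optical(va, remote_frame, -5.0, -1.5)
            np.testing.assert_allclose(back, oa, atol=1e-9)
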