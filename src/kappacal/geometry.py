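"""Coordinate frames and the angular eye-axis model.

The eyeball coordinate system is anchored at the corneal center with its
x- and y-axes parallel to the screen's horizontal and vertical edges and
its z-axis normal to the screen, pointing from the screen toward the eye.
In that frame a unit gaze direction is parameterised by a horizontal
angle ``omega`` and a vertical angle ``phi``::

    v = (cos(phi) sin(omega), sin(phi), -cos(phi) cos(omega))

so ``omega = phi = 0`` looks straight at the screen (along -z).  The
visual axis (the true gaze, through the fovea) is obtained from the
reconstructible optical axis by adding the per-eye kappa angle
``(alpha, beta)`` to ``(omega, phi)``.

All public interfaces take and return degrees; radians are used only
internally.  Points are in millimetres in the camera frame unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "GimbalLockError",
    "AngularPose",
    "KappaAngles",
    "EyeballFrame",
    "unit",
    "ordered_corners",
    "build_eyeball_frame",
    "direction_to_eyeball",
    "direction_to_camera",
    "angles_from_direction",
    "direction_from_angles",
    "visual_axis_from_optical",
    "wrap_angle",
]

_UNIT_TOL = 1e-9
_COPLANAR_TOL = 1e-6


class GeometryError(ValueError):
    """Degenerate or inconsistent geometric input."""


class GimbalLockError(GeometryError):
    """Vertical angle at/beyond +-90 deg: outside the angular model's domain."""


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` scaled to unit norm.

    Raises :class:`GeometryError` on a (near-)zero vector.
    """
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("cannot normalise a zero vector")
    return v / n


def _check_unit(v: np.ndarray, name: str = "direction") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise GeometryError(f"{name} must be a 3-vector, got shape {v.shape}")
    if abs(np.linalg.norm(v) - 1.0) > _UNIT_TOL:
        raise GeometryError(f"{name} must have unit norm (|v| = {np.linalg.norm(v):.6g})")
    return v


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    wrapped = math.fmod(deg + 180.0, 360.0)
    if wrapped <= 0.0:
        wrapped += 360.0
    return wrapped - 180.0


@dataclass(frozen=True)
class AngularPose:
    """Horizontal/vertical angles (degrees) of a gaze direction.

    ``omega`` is the horizontal angle (positive toward the screen-frame
    +x), wrapped to (-180, 180]; ``phi`` the vertical angle (positive
    up), restricted to the open interval (-90, 90).
    """

    omega: float
    phi: float

    def __post_init__(self) -> None:
        if not (-90.0 < self.phi < 90.0):
            raise GimbalLockError(f"phi must lie in (-90, 90) deg, got {self.phi}")
        object.__setattr__(self, "omega", wrap_angle(self.omega))


@dataclass(frozen=True)
class KappaAngles:
    """Per-eye kappa angle: horizontal alpha and vertical beta, degrees."""

    alpha_left: float
    beta_left: float
    alpha_right: float
    beta_right: float

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not math.isfinite(value):
                raise ValueError(f"kappa component {name} must be finite")

    @classmethod
    def from_array(cls, x) -> "KappaAngles":
        x = np.asarray(x, dtype=float).reshape(4)
        return cls(*x.tolist())

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha_left, self.beta_left, self.alpha_right, self.beta_right]
        )

    @property
    def left(self) -> tuple[float, float]:
        return (self.alpha_left, self.beta_left)

    @property
    def right(self) -> tuple[float, float]:
        return (self.alpha_right, self.beta_right)


@dataclass(frozen=True)
class EyeballFrame:
    """Orthonormal eyeball frame: rotation (camera -> eyeball) + origin.

    ``rotation`` rows are the frame's x/y/z axes expressed in camera
    coordinates, so ``rotation @ v`` converts a camera-frame direction
    into the eyeball frame.  Directions transform with the rotation
    alone; the translation applies to points only.
    """

    rotation: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3):
            raise GeometryError("rotation must be 3x3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise GeometryError("rotation must be orthonormal")
        if np.linalg.det(r) < 0:
            raise GeometryError("rotation must be right-handed (det = +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    def direction_to_eyeball(self, v_camera) -> np.ndarray:
        return self.rotation @ np.asarray(v_camera, dtype=float)

    def direction_to_camera(self, v_eyeball) -> np.ndarray:
        return self.rotation.T @ np.asarray(v_eyeball, dtype=float)

    def point_to_eyeball(self, p_camera) -> np.ndarray:
        return self.rotation @ (np.asarray(p_camera, dtype=float) - self.origin)

    def point_to_camera(self, p_eyeball) -> np.ndarray:
        return self.rotation.T @ np.asarray(p_eyeball, dtype=float) + self.origin


# ---------------------------------------------------------------------------
# screen rectangle handling


def _rectangle_cycle(corners: np.ndarray) -> np.ndarray:
    """Re-order four corners into a simple rectangle cycle, keeping corner 0 first.

    The input may list the corners in cycle order already or in a
    "crossed" order; only the three pairings that keep corner 0 first are
    tried.  Raises :class:`GeometryError` if none forms a rectangle.
    """
    for order in ((0, 1, 2, 3), (0, 1, 3, 2), (0, 2, 1, 3)):
        c = corners[list(order)]
        e01 = c[1] - c[0]
        e12 = c[2] - c[1]
        e32 = c[2] - c[3]
        e03 = c[3] - c[0]
        if np.linalg.norm(e01) < 1e-9 or np.linalg.norm(e03) < 1e-9:
            continue
        opposite_ok = np.allclose(e01, e32, atol=1e-6) and np.allclose(
            e03, c[2] - c[1], atol=1e-6
        )
        orthogonal_ok = abs(np.dot(e01, e12)) <= 1e-6 * max(
            np.linalg.norm(e01) * np.linalg.norm(e12), 1.0
        )
        if opposite_ok and orthogonal_ok:
            return c
    raise GeometryError("the four corners do not form a rectangle")


def ordered_corners(screen_corners) -> np.ndarray:
    """Return screen corners ordered (top-left, top-right, bottom-right, bottom-left).

    The first edge of the supplied cycle is taken as the screen-horizontal
    direction; the vertical edge is oriented upward by the sign of its dot
    product with the camera +y axis (kept as supplied when exactly
    perpendicular, e.g. a screen rolled by 90 deg).
    """
    corners = np.asarray(screen_corners, dtype=float)
    if corners.shape != (4, 3):
        raise GeometryError("screen_corners must be 4 points of 3 coordinates")
    if len({tuple(np.round(c, 9)) for c in corners}) < 4:
        raise GeometryError("screen corners contain coincident points")
    cycle = _rectangle_cycle(corners)
    # coplanarity is implied by the rectangle check, but verify explicitly
    n = np.cross(cycle[1] - cycle[0], cycle[3] - cycle[0])
    if abs(np.dot(unit(n), cycle[2] - cycle[0])) > _COPLANAR_TOL:
        raise GeometryError("screen corners are not coplanar")
    x_dir = unit(cycle[1] - cycle[0])
    up = unit(cycle[0] - cycle[3])  # corner 0 treated as on the top edge
    if np.dot(up, [0.0, 1.0, 0.0]) < -_UNIT_TOL:
        up = -up  # supplied cycle started on the bottom edge: flip
    center = cycle.mean(axis=0)
    xs = (cycle - center) @ x_dir
    ys = (cycle - center) @ up
    tl = cycle[np.lexsort((xs, -ys))[0]]
    tr = cycle[np.lexsort((-xs, -ys))[0]]
    br = cycle[np.lexsort((-xs, ys))[0]]
    bl = cycle[np.lexsort((xs, ys))[0]]
    return np.array([tl, tr, br, bl])


def build_eyeball_frame(screen_corners, corneal_center) -> EyeballFrame:
    """Construct the eyeball frame from the screen rectangle and corneal center.

    x-axis: unit vector along the screen's horizontal edge; y-axis: unit
    vector along the vertical edge, oriented upward; z-axis completes a
    right-handed frame and points from the screen toward the corneal
    center (x is flipped to preserve handedness if the initial z points
    away).  The origin is the corneal center.
    """
    tl, tr, br, bl = ordered_corners(screen_corners)
    c = np.asarray(corneal_center, dtype=float)
    x_axis = unit(tr - tl)
    y_axis = unit(tl - bl)
    if abs(np.dot(x_axis, y_axis)) > 1e-6:
        raise GeometryError("screen edges are not orthogonal")
    z_axis = np.cross(x_axis, y_axis)
    center = (tl + tr + br + bl) / 4.0
    towards_eye = float(np.dot(z_axis, c - center))
    if abs(towards_eye) < _COPLANAR_TOL:
        raise GeometryError("corneal center lies on the screen plane")
    if towards_eye < 0:
        x_axis = -x_axis
        z_axis = -z_axis
    return EyeballFrame(rotation=np.vstack([x_axis, y_axis, z_axis]), origin=c)


# ---------------------------------------------------------------------------
# angular representation


def direction_to_eyeball(frame: EyeballFrame, v_camera) -> np.ndarray:
    """Rotate a unit camera-frame direction into the eyeball frame."""
    return frame.direction_to_eyeball(_check_unit(v_camera, "v_camera"))


def direction_to_camera(frame: EyeballFrame, v_eyeball) -> np.ndarray:
    """Rotate a unit eyeball-frame direction back into the camera frame."""
    return frame.direction_to_camera(_check_unit(v_eyeball, "v_eyeball"))


def angles_from_direction(v_eyeball) -> AngularPose:
    """Recover (omega, phi) in degrees from a unit eyeball-frame direction.

    phi = arcsin(y); omega = atan2(x, -z), covering all quadrants.
    Directions within 1e-12 of straight up/down are rejected (gimbal
    lock: omega is undefined there).
    """
    v = _check_unit(v_eyeball, "v_eyeball")
    x, y, z = v
    if abs(y) >= 1.0 - 1e-12:
        raise GimbalLockError("vertical gaze: |y| >= 1 - 1e-12, omega undefined")
    phi = math.asin(max(-1.0, min(1.0, y)))
    omega = math.atan2(x, -z)
    return AngularPose(omega=math.degrees(omega), phi=math.degrees(phi))


def direction_from_angles(pose: AngularPose | tuple[float, float]) -> np.ndarray:
    """Unit eyeball-frame direction for angles (omega, phi) in degrees."""
    if not isinstance(pose, AngularPose):
        pose = AngularPose(*pose)
    w = math.radians(pose.omega)
    p = math.radians(pose.phi)
    return np.array(
        [math.cos(p) * math.sin(w), math.sin(p), -math.cos(p) * math.cos(w)]
    )


def visual_axis_from_optical(
    v_oa_camera, frame: EyeballFrame, alpha: float, beta: float
) -> np.ndarray:
    """The visual-axis synthesis h(Voa, C; alpha, beta).

    Converts the optical-axis direction into the eyeball frame, extracts
    its (omega, phi), forms the visual-axis angles (omega + alpha,
    phi + beta), rebuilds the direction and rotates it back to the camera
    frame.  alpha/beta in degrees.  Unit norm in, unit norm out.
    """
    oa_eye = direction_to_eyeball(frame, v_oa_camera)
    pose = angles_from_direction(oa_eye)
    va_eye = direction_from_angles(AngularPose(pose.omega + alpha, pose.phi + beta))
    return frame.direction_to_camera(va_eye)
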