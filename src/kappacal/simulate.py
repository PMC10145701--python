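"""Synthetic binocular gaze-scene generation.

Builds ground-truth test data for the calibrator without any recorded
eye-tracking data: corneal centers are drawn in a configured box, gaze
points uniformly on the screen rectangle, the visual axis of each eye is
the line from its corneal center to the gaze point, and the optical axis
is constructed *in reverse* by subtracting the ground-truth kappa angle
from the visual-axis angles in the eyeball frame.  Gaussian measurement
noise can then be injected into the corneal centers (mm) or into the
optical-axis angles (degrees).

Only corneal centers and axis directions are modelled; the schematic-eye
optics (corneal refraction, pupil imaging) that motivate the parameter
ranges are not traced.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .geometry import (
    AngularPose,
    EyeballFrame,
    GeometryError,
    KappaAngles,
    angles_from_direction,
    build_eyeball_frame,
    direction_from_angles,
    ordered_corners,
    unit,
)

__all__ = [
    "SceneConfig",
    "NoiseConfig",
    "BinocularSample",
    "sample_corneal_pair",
    "sample_gaze_points",
    "synthesize_sample",
    "generate_dataset",
    "add_corneal_noise",
    "add_oa_noise",
    "perturb_dataset",
]


@dataclass(frozen=True)
class BinocularSample:
    """One binocular gaze instant: corneal centers + optical-axis directions.

    ``gaze_point`` is present for synthetic/ground-truth data and absent
    for calibration-only input.
    """

    c_left: np.ndarray
    c_right: np.ndarray
    v_oa_left: np.ndarray
    v_oa_right: np.ndarray
    gaze_point: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("c_left", "c_right", "v_oa_left", "v_oa_right"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("v_oa_left", "v_oa_right"):
            v = getattr(self, name)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise GeometryError(f"{name} must be a unit vector")
        if self.gaze_point is not None:
            object.__setattr__(self, "gaze_point", np.asarray(self.gaze_point, dtype=float))

    @property
    def baseline(self) -> np.ndarray:
        """The corneal baseline C_L - C_R (mm, camera frame)."""
        return self.c_left - self.c_right


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and ground truth of a simulated binocular scene.

    ``left_center_box`` gives per-coordinate (lo, hi) intervals (mm) for
    the left corneal center; the right center sits ``interocular_distance``
    away along a random direction within ``cone_half_angle_deg`` of the
    screen-horizontal axis, keeping the eyes side by side.
    """

    screen_corners: np.ndarray
    left_center_box: tuple[tuple[float, float], ...]
    kappa_truth: KappaAngles
    interocular_distance: float = 60.0
    cone_half_angle_deg: float = 30.0

    def __post_init__(self) -> None:
        corners = ordered_corners(self.screen_corners)  # validates the rectangle
        object.__setattr__(self, "screen_corners", corners)
        box = tuple((float(lo), float(hi)) for lo, hi in self.left_center_box)
        if len(box) != 3 or any(hi < lo for lo, hi in box):
            raise ValueError("left_center_box must be three non-empty (lo, hi) intervals")
        object.__setattr__(self, "left_center_box", box)
        if self.interocular_distance <= 0:
            raise ValueError("interocular_distance must be positive")


@dataclass(frozen=True)
class NoiseConfig:
    """Gaussian measurement-noise levels: corneal SD in mm, axis-angle SD in deg."""

    corneal_sd: float = 0.0
    oa_angle_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.corneal_sd < 0 or self.oa_angle_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _screen_x_axis(screen_corners: np.ndarray) -> np.ndarray:
    tl, tr, _, _ = ordered_corners(screen_corners)
    return unit(tr - tl)


def sample_corneal_pair(
    config: SceneConfig, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a left corneal center in the box and place the right eye 60 mm away.

    The offset direction is uniform within a cone of half-angle
    ``config.cone_half_angle_deg`` about the screen-horizontal axis and
    is scaled to ``config.interocular_distance`` exactly.
    """
    rng = _as_rng(rng)
    lo = np.array([iv[0] for iv in config.left_center_box])
    hi = np.array([iv[1] for iv in config.left_center_box])
    c_left = lo + (hi - lo) * rng.uniform(size=3)
    axis = _screen_x_axis(config.screen_corners)
    half = np.radians(config.cone_half_angle_deg)
    # uniform over the spherical cap: cos(theta) ~ U[cos(half), 1]
    cos_t = 1.0 - rng.uniform() * (1.0 - np.cos(half))
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t**2))
    psi = rng.uniform(0.0, 2.0 * np.pi)
    # orthonormal basis completing the cone axis
    helper = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 0.0, 1.0])
    e1 = unit(np.cross(axis, helper))
    e2 = np.cross(axis, e1)
    direction = cos_t * axis + sin_t * (np.cos(psi) * e1 + np.sin(psi) * e2)
    c_right = c_left + config.interocular_distance * direction
    return c_left, c_right


def sample_gaze_points(
    screen_corners, n: int, rng, region: Optional[int] = None
) -> np.ndarray:
    """Draw ``n`` gaze points uniformly on the screen rectangle (or one quadrant).

    Points are bilinear combinations of the corners.  ``region`` selects
    a quadrant (screen split at the midlines of both axes), numbered
    row-major from the top-left: 1 = top-left, 2 = top-right,
    3 = bottom-left, 4 = bottom-right.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(rng)
    tl, tr, _, bl = ordered_corners(screen_corners)
    u_lo, u_hi, v_lo, v_hi = 0.0, 1.0, 0.0, 1.0
    if region is not None:
        if region not in (1, 2, 3, 4):
            raise ValueError(f"region must be 1..4, got {region}")
        u_lo, u_hi = (0.0, 0.5) if region in (1, 3) else (0.5, 1.0)
        v_lo, v_hi = (0.0, 0.5) if region in (1, 2) else (0.5, 1.0)
    u = rng.uniform(u_lo, u_hi, size=n)
    v = rng.uniform(v_lo, v_hi, size=n)
    return tl + u[:, None] * (tr - tl) + v[:, None] * (bl - tl)


def _oa_from_va(
    va_camera: np.ndarray, frame: EyeballFrame, alpha: float, beta: float
) -> np.ndarray:
    """Invert the kappa offset: optical-axis direction whose visual axis is ``va``."""
    pose = angles_from_direction(frame.direction_to_eyeball(va_camera))
    oa_eye = direction_from_angles(AngularPose(pose.omega - alpha, pose.phi - beta))
    return frame.direction_to_camera(oa_eye)


def synthesize_sample(
    c_left, c_right, gaze_point, kappa_truth: KappaAngles, screen_corners
) -> BinocularSample:
    """Construct a noiseless sample whose visual axes meet at ``gaze_point``.

    Per eye, the visual axis is the unit vector from the corneal center
    to the gaze point; the optical axis is rebuilt in reverse by
    subtracting that eye's (alpha, beta) from the visual-axis angles in
    the eyeball frame.
    """
    c_left = np.asarray(c_left, dtype=float)
    c_right = np.asarray(c_right, dtype=float)
    gaze_point = np.asarray(gaze_point, dtype=float)
    frame = build_eyeball_frame(screen_corners, c_left)
    va_left = unit(gaze_point - c_left)
    va_right = unit(gaze_point - c_right)
    oa_left = _oa_from_va(va_left, frame, *kappa_truth.left)
    oa_right = _oa_from_va(va_right, frame, *kappa_truth.right)
    return BinocularSample(c_left, c_right, oa_left, oa_right, gaze_point)


def add_corneal_noise(sample: BinocularSample, sd_mm: float, rng) -> BinocularSample:
    """Add independent N(0, sd^2) noise to all six corneal-center coordinates."""
    if sd_mm < 0:
        raise ValueError("sd_mm must be >= 0")
    if sd_mm == 0:
        return sample
    rng = _as_rng(rng)
    return replace(
        sample,
        c_left=sample.c_left + rng.normal(0.0, sd_mm, size=3),
        c_right=sample.c_right + rng.normal(0.0, sd_mm, size=3),
    )


def add_oa_noise(
    sample: BinocularSample, sd_deg: float, rng, screen_corners
) -> BinocularSample:
    """Perturb each eye's optical-axis angles by independent N(0, sd^2) deg.

    The axis direction is converted to the eyeball frame, noise is added
    to its horizontal and vertical angles, and the direction is rebuilt.
    """
    if sd_deg < 0:
        raise ValueError("sd_deg must be >= 0")
    if sd_deg == 0:
        return sample
    rng = _as_rng(rng)
    frame = build_eyeball_frame(screen_corners, sample.c_left)

    def noisy(v_oa: np.ndarray) -> np.ndarray:
        pose = angles_from_direction(frame.direction_to_eyeball(v_oa))
        jitter = rng.normal(0.0, sd_deg, size=2)
        perturbed = AngularPose(pose.omega + jitter[0], pose.phi + jitter[1])
        return frame.direction_to_camera(direction_from_angles(perturbed))

    return replace(
        sample, v_oa_left=noisy(sample.v_oa_left), v_oa_right=noisy(sample.v_oa_right)
    )


def perturb_dataset(
    samples: Sequence[BinocularSample],
    noise: NoiseConfig,
    rng,
    screen_corners,
) -> list[BinocularSample]:
    """Apply corneal then axis-angle noise to every sample of a dataset."""
    rng = _as_rng(rng)
    out = []
    for s in samples:
        s = add_corneal_noise(s, noise.corneal_sd, rng)
        s = add_oa_noise(s, noise.oa_angle_sd, rng, screen_corners)
        out.append(s)
    return out


def generate_dataset(
    config: SceneConfig,
    n_samples: int,
    rng,
    noise: Optional[NoiseConfig] = None,
    fixed_corneal_pair: Optional[tuple[np.ndarray, np.ndarray]] = None,
    region: Optional[int] = None,
) -> list[BinocularSample]:
    """Generate ``n_samples`` binocular samples for a scene.

    Each sample gets a fresh corneal pair and gaze point unless
    ``fixed_corneal_pair`` pins the head (the fixed-head gaze-region
    protocol uses one printed pair for every gaze point).  Noise, when
    given, is applied after the exact synthesis.  Deterministic for a
    fixed rng seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = _as_rng(rng)
    gaze_points = sample_gaze_points(config.screen_corners, n_samples, rng, region)
    samples = []
    for g in gaze_points:
        if fixed_corneal_pair is not None:
            c_left, c_right = fixed_corneal_pair
        else:
            c_left, c_right = sample_corneal_pair(config, rng)
        samples.append(
            synthesize_sample(c_left, c_right, g, config.kappa_truth, config.screen_corners)
        )
    if noise is not None:
        samples = perturb_dataset(samples, noise, rng, config.screen_corners)
    return samples
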