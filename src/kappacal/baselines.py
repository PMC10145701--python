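"""Reference kappa calibrators requiring explicit calibration points.

Three comparison methods:

* matrix method — fit a 3x3 transform M with Vva = M Voa over N >= 3
  known optical/visual-axis pairs (multi-point explicit calibration);
* angular method — invert the angle superposition from a single sample
  with a known gaze point, giving (alpha, beta) per eye;
* constant method — skip calibration and use the population-average
  kappa (5, 1.5, -5, 1.5) deg.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .geometry import (
    KappaAngles,
    angles_from_direction,
    build_eyeball_frame,
    unit,
    wrap_angle,
)
from .simulate import BinocularSample

__all__ = [
    "fit_matrix_method",
    "fit_angular_method",
    "constant_kappa",
]


def fit_matrix_method(v_oa: Sequence, v_va: Sequence) -> np.ndarray:
    """Least-squares 3x3 transform mapping optical to visual axes.

    Solves M Voa ~= Vva over the 3xN stacked direction matrices by
    ordinary least squares (no orthogonality constraint).  Requires at
    least three pairs with a rank-3 optical-axis set; with exactly three
    consistent pairs the fit is exact.
    """
    oa = np.asarray(v_oa, dtype=float)
    va = np.asarray(v_va, dtype=float)
    if oa.ndim != 2 or oa.shape[1] != 3 or oa.shape != va.shape:
        raise ValueError("expected matching (N, 3) arrays of directions")
    if oa.shape[0] < 3:
        raise ValueError("the matrix method needs at least three calibration points")
    if np.linalg.matrix_rank(oa) < 3:
        raise ValueError("optical-axis set is rank-deficient; directions are coplanar")
    m_t, *_ = np.linalg.lstsq(oa, va, rcond=None)
    return m_t.T


def fit_angular_method(sample: BinocularSample, screen_corners) -> KappaAngles:
    """Single-point angular calibration: kappa from one sample with a gaze point.

    Per eye the visual axis is the unit vector from the corneal center
    to the (known) gaze point; alpha/beta are the differences of the
    visual- and optical-axis angles in the eyeball frame, wrapped to
    (-180, 180].
    """
    if sample.gaze_point is None:
        raise ValueError("the angular method needs a sample with a known gaze point")
    frame = build_eyeball_frame(screen_corners, sample.c_left)

    def eye(c: np.ndarray, v_oa: np.ndarray) -> tuple[float, float]:
        va = unit(sample.gaze_point - c)
        pose_va = angles_from_direction(frame.direction_to_eyeball(va))
        pose_oa = angles_from_direction(frame.direction_to_eyeball(v_oa))
        return (
            wrap_angle(pose_va.omega - pose_oa.omega),
            pose_va.phi - pose_oa.phi,
        )

    alpha_l, beta_l = eye(sample.c_left, sample.v_oa_left)
    alpha_r, beta_r = eye(sample.c_right, sample.v_oa_right)
    return KappaAngles(alpha_l, beta_l, alpha_r, beta_r)


def constant_kappa() -> KappaAngles:
    """The calibration-free constant: (5, 1.5, -5, 1.5) deg."""
    return KappaAngles(5.0, 1.5, -5.0, 1.5)
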