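"""Canonical scene and solver presets.

Two simulated gaze-tracking setups are shipped:

* ``remote``: a desktop screen (400 x 300 mm, tilted ~40 deg about the
  camera x-axis) viewed from 350-650 mm, the camera between user and
  screen.
* ``head_mounted``: a near-eye display plane 400+ mm behind the camera
  origin with the corneal centers a few centimetres in front of it.

Both fix the interocular (corneal baseline) distance at 60 mm and use a
ground-truth kappa of (+5, 1.5) deg for the left eye and (-5, 1.5) deg
for the right (horizontal components mirrored between eyes, matching
population averages of ~5 deg horizontal / ~1.5 deg vertical).
"""

from __future__ import annotations

import numpy as np

from .calibrate import DEConfig
from .geometry import KappaAngles
from .simulate import SceneConfig

__all__ = [
    "DEFAULT_KAPPA_TRUTH",
    "REMOTE_SCREEN_CORNERS",
    "HEAD_MOUNTED_SCREEN_CORNERS",
    "FIXED_CORNEAL_PAIR",
    "remote_scene",
    "head_mounted_scene",
    "scene_preset",
    "theoretical_de_config",
    "practical_de_config",
]

DEFAULT_KAPPA_TRUTH = KappaAngles(5.0, 1.5, -5.0, 1.5)

#: Remote-setup screen rectangle (mm, camera frame), listed
#: top-left, top-right, bottom-right, bottom-left.
REMOTE_SCREEN_CORNERS = np.array(
    [
        [-200.0, 262.045317, 250.064495],
        [200.0, 262.045317, 250.064495],
        [200.0, 69.209034, 20.251162],
        [-200.0, 69.209034, 20.251162],
    ]
)

#: Generation box for the left corneal center in the remote setup (mm).
REMOTE_LEFT_BOX = ((-45.0, -15.0), (-90.0, -50.0), (350.0, 650.0))

#: Head-mounted-setup screen rectangle (mm, camera frame).
HEAD_MOUNTED_SCREEN_CORNERS = np.array(
    [
        [-75.0, 70.0, -400.0],
        [225.0, 70.0, -400.0],
        [225.0, -140.0, -400.0],
        [-75.0, -140.0, -400.0],
    ]
)

HEAD_MOUNTED_LEFT_BOX = ((5.0, 10.0), (20.0, 30.0), (25.0, 35.0))

#: A fixed left/right corneal-center pair (mm) used by the fixed-head
#: gaze-region protocol; the pair satisfies the 60 mm baseline constraint.
FIXED_CORNEAL_PAIR = (
    np.array([-33.62420733, -62.55917489, 508.7146057]),
    np.array([24.63352113, -76.53688391, 505.449529]),
)


def remote_scene(kappa_truth: KappaAngles = DEFAULT_KAPPA_TRUTH) -> SceneConfig:
    """Scene configuration for the remote (desktop) setup."""
    return SceneConfig(
        screen_corners=REMOTE_SCREEN_CORNERS,
        left_center_box=REMOTE_LEFT_BOX,
        kappa_truth=kappa_truth,
    )


def head_mounted_scene(kappa_truth: KappaAngles = DEFAULT_KAPPA_TRUTH) -> SceneConfig:
    """Scene configuration for the head-mounted (near-eye) setup."""
    return SceneConfig(
        screen_corners=HEAD_MOUNTED_SCREEN_CORNERS,
        left_center_box=HEAD_MOUNTED_LEFT_BOX,
        kappa_truth=kappa_truth,
    )


def scene_preset(name: str, kappa_truth: KappaAngles = DEFAULT_KAPPA_TRUTH) -> SceneConfig:
    """Look up a scene preset by name ('remote' or 'head_mounted')."""
    presets = {"remote": remote_scene, "head_mounted": head_mounted_scene}
    key = name.replace("-", "_")
    if key not in presets:
        raise ValueError(f"unknown scene preset {name!r}; choose from {sorted(presets)}")
    return presets[key](kappa_truth)


def theoretical_de_config(seed: int | None = None) -> DEConfig:
    """Solver constants for simulation within the theoretical kappa range.

    Population 35, mutation 0.5, crossover 1, termination error 1e-9,
    bounds 4..8 / 0..3 / -8..-4 / 0..3 deg for (alphaL, betaL, alphaR,
    betaR).
    """
    return DEConfig(
        population_size=35,
        mutation=0.5,
        crossover=1.0,
        bounds=((4.0, 8.0), (0.0, 3.0), (-8.0, -4.0), (0.0, 3.0)),
        termination_error=1e-9,
        seed=seed,
    )


def practical_de_config(seed: int | None = None) -> DEConfig:
    """Refined-search constants for noisy, real-scene data.

    Small mutation (0.01) and crossover gate (0.1), symmetric +-5 deg
    bounds on every component.
    """
    return DEConfig(
        population_size=35,
        mutation=0.01,
        crossover=0.1,
        bounds=((-5.0, 5.0),) * 4,
        termination_error=1e-9,
        seed=seed,
    )
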