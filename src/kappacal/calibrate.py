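"""Automatic kappa-angle calibration from binocular observations.

The binocular gaze constraint: when both eyes fixate one on-screen
point, the two visual axes span a *gaze plane* and the corneal baseline
C_L - C_R lies in it (both corneal centers are on their eye's visual
axis).  For candidate kappa angles x = (alphaL, betaL, alphaR, betaR)
the visual axes are synthesised from the observed optical axes, and the
calibration minimises the gaze-constraint error

    f(x) = sum_i ( n_i(x) . (C_iL - C_iR) )^2,
    n_i  = VvaL x VvaR / ||VvaL x VvaR||,

over N >= 4 samples, using a differential-evolution (DE) search inside
the theoretical per-component kappa bounds.  DE avoids any dependence on
an initial guess: a population of W candidate vectors evolves by
mutation v = x_r1 + K (x_r2 - x_r3) (clamped to the bounds), a
whole-vector crossover gate c, and greedy selection, until the best
error drops below the termination error delta.

The cross product and dot product are rotation-invariant, so the
objective is evaluated in the eyeball frame, where the per-sample
optical-axis angles can be precomputed once; candidate evaluation is
then fully vectorised (:class:`CoplanarityObjective`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import GeometryError, KappaAngles, build_eyeball_frame
from .simulate import BinocularSample

__all__ = [
    "DEGENERATE_PENALTY",
    "CalibrationError",
    "DEConfig",
    "Population",
    "CalibrationResult",
    "CoplanarityObjective",
    "gaze_plane_normal",
    "gaze_constraint_error",
    "init_population",
    "mutate",
    "crossover",
    "select",
    "calibrate",
    "grid_search_kappa",
]

#: Objective value assigned to a candidate that makes some sample's
#: visual axes (near-)parallel (no gaze plane).  Keeps the population
#: iterable; a final result must never be penalty-valued.
DEGENERATE_PENALTY = 1e6

_PARALLEL_TOL = 1e-12


class CalibrationError(RuntimeError):
    """Calibration could not produce a usable kappa estimate."""


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution constants.

    population_size
        Number of candidate kappa vectors W (>= 4 so that three distinct
        mutation partners other than k exist).
    mutation
        Scale K of the difference vector in v = x_r1 + K (x_r2 - x_r3).
    crossover
        Gate c in [0, 1]: per candidate per generation one uniform draw
        decides between the whole mutated vector and the parent.
    bounds
        Per-component (lower, upper) limits in degrees for
        (alphaL, betaL, alphaR, betaR); candidates are clamped to them.
    termination_error
        delta: stop once the best gaze-constraint error falls below it.
    max_iterations
        Generation cap T.
    binomial_crossover
        Optional per-component crossover variant (canonical DE/rand/1/bin);
        the default mixes whole vectors.
    """

    population_size: int = 35
    mutation: float = 0.5
    crossover: float = 1.0
    bounds: tuple[tuple[float, float], ...] = (
        (4.0, 8.0),
        (0.0, 3.0),
        (-8.0, -4.0),
        (0.0, 3.0),
    )
    termination_error: float = 1e-9
    max_iterations: int = 1000
    seed: Optional[int] = None
    binomial_crossover: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if not 0.0 <= self.crossover <= 1.0:
            raise ValueError("crossover must lie in [0, 1]")
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        if len(bounds) != 4 or any(lo >= hi for lo, hi in bounds):
            # collapsed bounds (lo == hi) are permitted for testing
            if len(bounds) != 4 or any(lo > hi for lo, hi in bounds):
                raise ValueError("bounds must be 4 pairs with lower <= upper")
        object.__setattr__(self, "bounds", bounds)
        if self.termination_error <= 0:
            raise ValueError("termination_error must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])


@dataclass
class Population:
    """The W candidate kappa vectors with their objective values."""

    vectors: np.ndarray  # (W, 4) degrees
    values: Optional[np.ndarray] = None  # (W,)
    best: Optional[np.ndarray] = None  # (4,)
    best_value: Optional[float] = None


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of one calibration run."""

    kappa: KappaAngles
    iterations_used: int
    final_error: float
    converged: bool
    history: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.final_error < 0:
            raise ValueError("final_error must be non-negative")


# ---------------------------------------------------------------------------
# objective


def gaze_plane_normal(v_va_left, v_va_right) -> np.ndarray:
    """Unit normal of the plane spanned by the two visual axes.

    Raises :class:`GeometryError` when the axes are (near-)parallel and
    no gaze plane exists.
    """
    n = np.cross(np.asarray(v_va_left, float), np.asarray(v_va_right, float))
    norm = np.linalg.norm(n)
    if norm < _PARALLEL_TOL:
        raise GeometryError("visual axes are parallel: gaze plane is degenerate")
    return n / norm


class CoplanarityObjective:
    """Vectorised gaze-constraint error over a fixed sample set.

    The per-sample optical-axis angles (omega, phi) and the corneal
    baseline, all in the eyeball frame, are precomputed once; calling the
    object with a (4,) kappa vector or a (W, 4) batch then costs a few
    trigonometric array operations.
    """

    def __init__(self, samples: Sequence[BinocularSample], frame_rotation) -> None:
        if len(samples) == 0:
            raise ValueError("at least one sample is required")
        rot = np.asarray(frame_rotation, dtype=float)
        oa_l = np.array([s.v_oa_left for s in samples]) @ rot.T
        oa_r = np.array([s.v_oa_right for s in samples]) @ rot.T
        for name, v in (("left", oa_l), ("right", oa_r)):
            if np.any(np.abs(v[:, 1]) >= 1.0 - 1e-12):
                raise GeometryError(f"{name} optical axis is vertical (gimbal lock)")
        self.omega_l = np.arctan2(oa_l[:, 0], -oa_l[:, 2])
        self.phi_l = np.arcsin(np.clip(oa_l[:, 1], -1.0, 1.0))
        self.omega_r = np.arctan2(oa_r[:, 0], -oa_r[:, 2])
        self.phi_r = np.arcsin(np.clip(oa_r[:, 1], -1.0, 1.0))
        self.baseline = np.array([s.baseline for s in samples]) @ rot.T
        self.n_samples = len(samples)

    @staticmethod
    def _axes(omega: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, ...]:
        cp = np.cos(phi)
        return cp * np.sin(omega), np.sin(phi), -cp * np.cos(omega)

    def __call__(self, kappa) -> np.ndarray | float:
        k = np.asarray(kappa, dtype=float)
        scalar = k.ndim == 1
        k = np.atleast_2d(np.radians(k))  # (W, 4)
        wl = self.omega_l[None, :] + k[:, 0:1]
        pl = self.phi_l[None, :] + k[:, 1:2]
        wr = self.omega_r[None, :] + k[:, 2:3]
        pr = self.phi_r[None, :] + k[:, 3:4]
        lx, ly, lz = self._axes(wl, pl)
        rx, ry, rz = self._axes(wr, pr)
        nx = ly * rz - lz * ry
        ny = lz * rx - lx * rz
        nz = lx * ry - ly * rx
        norm = np.sqrt(nx**2 + ny**2 + nz**2)
        degenerate = np.any(norm < _PARALLEL_TOL, axis=1)
        # a phi pushed to/past +-90 deg leaves the angular model's domain
        out_of_domain = np.any(np.abs(pl) >= np.pi / 2, axis=1) | np.any(
            np.abs(pr) >= np.pi / 2, axis=1
        )
        safe_norm = np.where(norm < _PARALLEL_TOL, 1.0, norm)
        b = self.baseline
        dots = (nx * b[None, :, 0] + ny * b[None, :, 1] + nz * b[None, :, 2]) / safe_norm
        f = np.einsum("wi,wi->w", dots, dots)
        f = np.where(degenerate | out_of_domain, DEGENERATE_PENALTY, f)
        return float(f[0]) if scalar else f


def gaze_constraint_error(
    samples: Sequence[BinocularSample], kappa: KappaAngles | np.ndarray, frame_rotation
) -> float:
    """Sum over samples of the squared normal-baseline dot product (Eq. f(x))."""
    k = kappa.as_array() if isinstance(kappa, KappaAngles) else np.asarray(kappa, float)
    return CoplanarityObjective(samples, frame_rotation)(k)


# ---------------------------------------------------------------------------
# differential-evolution primitives


def init_population(
    config: DEConfig, rng, objective: Optional[CoplanarityObjective] = None
) -> Population:
    """Draw W candidates component-uniform within the bounds.

    With an objective supplied, the per-candidate errors and the initial
    best-so-far vector (the argmin) are filled in.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lo, hi = config.lower, config.upper
    vectors = lo + (hi - lo) * rng.uniform(size=(config.population_size, 4))
    pop = Population(vectors=vectors)
    if objective is not None:
        pop.values = np.asarray(objective(vectors))
        k = int(np.argmin(pop.values))
        pop.best = vectors[k].copy()
        pop.best_value = float(pop.values[k])
    return pop


def _partners(rng: np.random.Generator, w: int, k: int) -> np.ndarray:
    """Three mutually distinct indices != k, uniform without replacement."""
    picks = rng.choice(w - 1, size=3, replace=False)
    return picks + (picks >= k)


def mutate(population: Population, k: int, config: DEConfig, rng) -> np.ndarray:
    """Difference mutation v = x_r1 + K (x_r2 - x_r3), clamped to the bounds."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = population.vectors
    if x.shape[0] < 4:
        raise ValueError("mutation needs a population of at least 4")
    r1, r2, r3 = _partners(rng, x.shape[0], k)
    v = x[r1] + config.mutation * (x[r2] - x[r3])
    return np.clip(v, config.lower, config.upper)


def crossover(x_k, v_k, c: float, rng, binomial: bool = False) -> np.ndarray:
    """Crossover gate: one uniform draw decides between the whole vectors.

    ``binomial=True`` switches to the canonical per-component variant.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x_k = np.asarray(x_k, float)
    v_k = np.asarray(v_k, float)
    if binomial:
        return np.where(rng.uniform(size=x_k.shape) <= c, v_k, x_k)
    return v_k.copy() if rng.uniform() <= c else x_k.copy()


def select(x_k, u_k, samples: Sequence[BinocularSample], frame_rotation) -> np.ndarray:
    """Greedy selection: keep whichever vector has the smaller error; ties keep x_k."""
    obj = CoplanarityObjective(samples, frame_rotation)
    x_k = np.asarray(x_k, float)
    u_k = np.asarray(u_k, float)
    return u_k.copy() if obj(u_k) < obj(x_k) else x_k.copy()


# ---------------------------------------------------------------------------
# the solver


def calibrate(
    samples: Sequence[BinocularSample],
    screen_corners,
    config: Optional[DEConfig] = None,
    keep_history: bool = True,
) -> CalibrationResult:
    """Calibrate the kappa angle from binocular samples.

    Runs the DE loop: initialise the population within the bounds, then
    per generation mutate/clamp, apply the crossover gate, select
    greedily, write the survivors back into the population and update
    the global best.  Stops when the best error drops below the
    termination error (the reported iteration count is the generation at
    which that first holds) or after ``max_iterations`` generations.

    One seeded generator drives initialisation, partner selection and
    crossover gates in a fixed call order, so runs are reproducible.
    """
    if config is None:
        config = DEConfig()
    n = len(samples)
    if n == 0:
        raise ValueError("at least one sample is required")
    if n < 4:
        warnings.warn(
            f"only {n} samples: four unknowns make the calibration underdetermined "
            "below N = 4",
            stacklevel=2,
        )
    rotation = build_eyeball_frame(screen_corners, samples[0].c_left).rotation
    objective = CoplanarityObjective(samples, rotation)
    rng = np.random.default_rng(config.seed)
    w = config.population_size
    lo, hi = config.lower, config.upper

    pop = init_population(config, rng, objective)
    x, fx = pop.vectors, pop.values
    best, best_value = pop.best, pop.best_value
    history = [best_value]
    iterations = 0
    converged = best_value < config.termination_error

    if not converged:
        for t in range(1, config.max_iterations + 1):
            idx = np.array([_partners(rng, w, k) for k in range(w)])
            v = x[idx[:, 0]] + config.mutation * (x[idx[:, 1]] - x[idx[:, 2]])
            np.clip(v, lo, hi, out=v)
            if config.binomial_crossover:
                gate = rng.uniform(size=(w, 4)) <= config.crossover
            else:
                gate = (rng.uniform(size=w) <= config.crossover)[:, None]
            u = np.where(gate, v, x)
            fu = np.asarray(objective(u))
            improved = fu < fx
            x = np.where(improved[:, None], u, x)
            fx = np.where(improved, fu, fx)
            k_best = int(np.argmin(fx))
            if fx[k_best] < best_value:
                best_value = float(fx[k_best])
                best = x[k_best].copy()
            if keep_history:
                history.append(best_value)
            iterations = t
            if best_value < config.termination_error:
                converged = True
                break

    if best_value >= DEGENERATE_PENALTY:
        raise CalibrationError(
            "every candidate left some sample without a gaze plane (parallel axes)"
        )
    return CalibrationResult(
        kappa=KappaAngles.from_array(best),
        iterations_used=iterations,
        final_error=best_value,
        converged=converged,
        history=tuple(history) if keep_history else (),
    )


def grid_search_kappa(
    samples: Sequence[BinocularSample],
    screen_corners,
    bounds: Sequence[tuple[float, float]],
    step: float = 0.05,
    chunk: int = 200_000,
) -> tuple[np.ndarray, float]:
    """Exhaustive minimisation of the gaze-constraint error on a regular grid.

    A brute-force cross-check for the DE solver on small problems;
    returns (argmin kappa vector, minimum error).
    """
    rotation = build_eyeball_frame(screen_corners, samples[0].c_left).rotation
    objective = CoplanarityObjective(samples, rotation)
    axes = [np.arange(lo, hi + step / 2, step) for lo, hi in bounds]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 4)
    best_val = np.inf
    best_k = grid[0]
    for start in range(0, grid.shape[0], chunk):
        block = grid[start : start + chunk]
        vals = np.asarray(objective(block))
        j = int(np.argmin(vals))
        if vals[j] < best_val:
            best_val = float(vals[j])
            best_k = block[j]
    return best_k.copy(), best_val
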