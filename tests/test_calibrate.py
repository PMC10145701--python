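import numpy as np
import pytest
from dataclasses import replace

import kappacal as kc
from kappacal.calibrate import (
    CoplanarityObjective,
    DEConfig,
    Population,
    crossover,
    gaze_constraint_error,
    gaze_plane_normal,
    init_population,
    mutate,
    select,
)
from kappacal.geometry import GeometryError, build_eyeball_frame


@pytest.fixture(scope="module")
def rotation(remote_scene, noiseless_remote_9):
    return build_eyeball_frame(
        remote_scene.screen_corners, noiseless_remote_9[0].c_left
    ).rotation


class TestGazePlaneNormal:
    def test_hand_computed_cross_product(self):
        n = gaze_plane_normal([0.0, 0.0, -1.0], np.array([1.0, 0.0, -1.0]) / np.sqrt(2))
        np.testing.assert_allclose(n, [0.0, -1.0, 0.0], atol=1e-15)

    def test_swapped_arguments_negate(self):
        a = np.array([0.1, 0.2, -0.97])
        a /= np.linalg.norm(a)
        b = np.array([-0.1, 0.15, -0.98])
        b /= np.linalg.norm(b)
        np.testing.assert_allclose(
            gaze_plane_normal(a, b), -gaze_plane_normal(b, a), atol=1e-15
        )

    def test_parallel_axes_degenerate(self):
        v = np.array([0.0, 0.0, -1.0])
        with pytest.raises(GeometryError):
            gaze_plane_normal(v, v)


class TestObjective:
    def test_nonnegative_everywhere(self, noiseless_remote_9, rotation, rng):
        obj = CoplanarityObjective(noiseless_remote_9, rotation)
        kappas = np.column_stack(
            [
                rng.uniform(4, 8, 50),
                rng.uniform(0, 3, 50),
                rng.uniform(-8, -4, 50),
                rng.uniform(0, 3, 50),
            ]
        )
        assert np.all(obj(kappas) >= 0)

    def test_increases_away_from_truth(self, noiseless_remote_9, rotation, remote_scene):
        truth = remote_scene.kappa_truth.as_array()
        obj = CoplanarityObjective(noiseless_remote_9, rotation)
        assert obj(truth + np.array([1.0, 0, 0, 0])) > obj(truth)

    def test_scalar_and_batch_paths_agree(self, noiseless_remote_9, rotation):
        obj = CoplanarityObjective(noiseless_remote_9, rotation)
        k = np.array([5.2, 1.1, -4.7, 1.9])
        assert obj(k) == pytest.approx(obj(k[None, :])[0], rel=1e-15)

    def test_left_right_swap_symmetry(self, noiseless_remote_9, rotation, remote_scene):
        """Swapping eye roles within samples together with swapping the kappa
        pairs leaves the squared triple product unchanged."""
        swapped = [
            replace(
                s,
                c_left=s.c_right,
                c_right=s.c_left,
                v_oa_left=s.v_oa_right,
                v_oa_right=s.v_oa_left,
            )
            for s in noiseless_remote_9
        ]
        k = np.array([5.3, 1.2, -4.6, 1.8])
        k_swapped = np.array([k[2], k[3], k[0], k[1]])
        a = gaze_constraint_error(noiseless_remote_9, k, rotation)
        b = gaze_constraint_error(swapped, k_swapped, rotation)
        assert a == pytest.approx(b, rel=1e-9)


class TestDEPrimitives:
    def test_collapsed_bounds_give_constant_population(self, rng):
        cfg = DEConfig(bounds=((5, 5), (1.5, 1.5), (-5, -5), (1.5, 1.5)))
        pop = init_population(cfg, rng)
        np.testing.assert_allclose(pop.vectors, [[5, 1.5, -5, 1.5]] * 35)

    def test_population_within_bounds(self, rng):
        cfg = kc.theoretical_de_config()
        pop = init_population(cfg, rng)
        assert np.all(pop.vectors >= cfg.lower) and np.all(pop.vectors <= cfg.upper)

    def test_population_reproducible(self):
        cfg = kc.theoretical_de_config()
        a = init_population(cfg, np.random.default_rng(5)).vectors
        b = init_population(cfg, np.random.default_rng(5)).vectors
        np.testing.assert_array_equal(a, b)

    def test_mutation_clamps_to_bounds(self, rng):
        cfg = kc.theoretical_de_config()
        vectors = np.tile([7.9, 1.0, -5.0, 1.0], (4, 1))
        vectors[1] = [7.9, 1.0, -5.0, 1.0]
        vectors[2] = [6.0, 1.0, -5.0, 1.0]
        vectors[3] = [5.0, 1.0, -5.0, 1.0]
        pop = Population(vectors=vectors)
        for _ in range(20):
            v = mutate(pop, 0, cfg, rng)
            assert np.all(v >= cfg.lower) and np.all(v <= cfg.upper)
        # arithmetic check of the clamp: 7.9 + 0.5 * 1.0 -> clamped at 8.0
        assert 7.9 + cfg.mutation * 1.0 > 8.0

    def test_zero_mutation_returns_partner(self, rng):
        cfg = replace(kc.theoretical_de_config(), mutation=0.0)
        vectors = np.array([[5, 1, -5, 1], [6, 2, -6, 2], [7, 1, -7, 1], [4, 0, -4, 0]], float)
        pop = Population(vectors=vectors)
        v = mutate(pop, 0, cfg, rng)
        assert any(np.allclose(v, vectors[i]) for i in (1, 2, 3))

    def test_identical_population_mutates_to_itself(self, rng):
        cfg = kc.theoretical_de_config()
        pop = Population(vectors=np.tile([5.0, 1.5, -5.0, 1.5], (6, 1)))
        np.testing.assert_allclose(mutate(pop, 2, cfg, rng), [5, 1.5, -5, 1.5])

    def test_crossover_extremes(self, rng):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([5.0, 6.0, 7.0, 8.0])
        for _ in range(200):
            np.testing.assert_array_equal(crossover(x, v, 1.0, rng), v)
            np.testing.assert_array_equal(crossover(x, v, 0.0, rng), x)

    def test_crossover_gate_fraction(self, rng):
        x = np.zeros(4)
        v = np.ones(4)
        picks = sum(crossover(x, v, 0.1, rng)[0] for _ in range(100_000))
        assert picks / 100_000 == pytest.approx(0.1, abs=0.01)

    def test_selection_greedy_with_ties_kept(
        self, noiseless_remote_9, rotation, remote_scene
    ):
        truth = remote_scene.kappa_truth.as_array()
        worse = truth + np.array([0.5, 0, 0, 0])
        corners = remote_scene.screen_corners
        np.testing.assert_array_equal(
            select(worse, truth, noiseless_remote_9, rotation), truth
        )
        np.testing.assert_array_equal(
            select(truth, worse, noiseless_remote_9, rotation), truth
        )
        np.testing.assert_array_equal(
            select(worse, worse.copy(), noiseless_remote_9, rotation), worse
        )


class TestCalibrate:
    def test_noiseless_recovery(self, remote_scene, noiseless_remote_9):
        res = kc.calibrate(
            noiseless_remote_9,
            remote_scene.screen_corners,
            kc.theoretical_de_config(seed=3),
        )
        assert res.converged and res.final_error < 1e-9
        np.testing.assert_allclose(
            res.kappa.as_array(), [5, 1.5, -5, 1.5], atol=0.01
        )

    def test_best_error_monotone_nonincreasing(self, remote_scene, noiseless_remote_9):
        res = kc.calibrate(
            noiseless_remote_9,
            remote_scene.screen_corners,
            kc.theoretical_de_config(seed=9),
        )
        h = np.array(res.history)
        assert np.all(np.diff(h) <= 0)

    def test_result_within_bounds(self, remote_scene, noiseless_remote_9):
        cfg = kc.theoretical_de_config(seed=11)
        res = kc.calibrate(noiseless_remote_9, remote_scene.screen_corners, cfg)
        k = res.kappa.as_array()
        assert np.all(k >= cfg.lower) and np.all(k <= cfg.upper)

    def test_empty_input_rejected(self, remote_scene):
        with pytest.raises(ValueError):
            kc.calibrate([], remote_scene.screen_corners)

    def test_underdetermined_single_sample_warns_and_scatters(self, remote_scene):
        """With one sample the four unknowns are underdetermined: runs may
        converge in objective yet scatter widely in kappa."""
        estimates = []
        for seed in range(6):
            data = kc.generate_dataset(remote_scene, 1, 1000 + seed)
            with pytest.warns(UserWarning, match="underdetermined"):
                res = kc.calibrate(
                    data, remote_scene.screen_corners, kc.theoretical_de_config(seed)
                )
            estimates.append(res.kappa)
        rmse = kc.kappa_rmse(estimates, remote_scene.kappa_truth)
        assert rmse.max() > 0.1  # far beyond the ~0.01 deg determined regime

    def test_grid_search_oracle_agrees_with_de(self, remote_scene, noiseless_remote_9):
        """Brute-force minimisation on a 0.05-deg grid around the bounds'
        interior locates the same minimiser as the evolutionary search."""
        res = kc.calibrate(
            noiseless_remote_9,
            remote_scene.screen_corners,
            kc.theoretical_de_config(seed=21),
        )
        k_grid, _ = kc.grid_search_kappa(
            noiseless_remote_9,
            remote_scene.screen_corners,
            bounds=[(4.5, 5.5), (1.0, 2.0), (-5.5, -4.5), (1.0, 2.0)],
            step=0.05,
        )
        np.testing.assert_allclose(res.kappa.as_array(), k_grid, atol=0.05)

    def test_matches_scipy_differential_evolution(
        self, remote_scene, noiseless_remote_9, rotation
    ):
        """Independent cross-check: scipy's DE finds the same minimiser."""
        scipy_opt = pytest.importorskip("scipy.optimize")
        obj = CoplanarityObjective(noiseless_remote_9, rotation)
        sp = scipy_opt.differential_evolution(
            lambda k: obj(k),
            bounds=[(4, 8), (0, 3), (-8, -4), (0, 3)],
            seed=2,
            tol=1e-12,
        )
        res = kc.calibrate(
            noiseless_remote_9,
            remote_scene.screen_corners,
            kc.theoretical_de_config(seed=2),
        )
        np.testing.assert_allclose(res.kappa.as_array(), sp.x, atol=0.01)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            DEConfig(population_size=3)
        with pytest.raises(ValueError):
            DEConfig(crossover=1.5)
        with pytest.raises(ValueError):
            DEConfig(termination_error=0.0)
        with pytest.raises(ValueError):
            DEConfig(bounds=((8, 4), (0, 3), (-8, -4), (0, 3)))
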