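import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clbso import CLBSOParams, run_clbso
from clbso.optimizer import (
    adaptive_weights,
    ant_local_search,
    comprehensive_update,
    grasshopper_move,
    initialize_population,
    levy_step,
    optimize,
    success_scores,
    toggle_probabilities,
    update_pheromone,
)


def popcount_fitness(mask):
    return float(np.sum(mask))


class TestInitializePopulation:
    def test_probability_one_gives_all_ones(self, small_rng):
        params = CLBSOParams(population_size=5, init_prob=0.999999999)
        pop = initialize_population(6, params, small_rng)
        assert pop.shape == (5, 6)
        assert pop.all()

    def test_probability_zero_repaired_to_single_gene(self, small_rng):
        params = CLBSOParams(population_size=8, init_prob=1e-12)
        pop = initialize_population(6, params, small_rng)
        assert (pop.sum(axis=1) == 1).all()

    def test_ones_count_within_binomial_concentration(self):
        """n=1000, p=.5: every mask's ones-count within 3 binomial SDs of 500."""
        rng = np.random.default_rng(5)
        params = CLBSOParams(population_size=50, init_prob=0.5)
        pop = initialize_population(1000, params, rng)
        counts = pop.sum(axis=1).astype(int)
        bound = 3 * np.sqrt(1000 * 0.25)  # ~47.4
        assert (np.abs(counts - 500) <= bound).all()


class TestUpdatePheromone:
    def test_noop_parameters_leave_tau_unchanged(self):
        tau = np.array([0.3, 0.6])
        pop = np.zeros((2, 2), dtype=np.uint8)
        out = update_pheromone(tau, pop, np.array([0.0, 0.0]), 0.0, rho=0.0)
        np.testing.assert_allclose(out, tau)

    def test_decay_plus_increment_arithmetic(self):
        """tau=.5, rho=.1, delta=.2 -> .65 (one of five masks carries the gene)."""
        tau = np.array([0.5])
        pop = np.array([[1], [0], [0], [0], [0]], dtype=np.uint8)
        fits = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        out = update_pheromone(tau, pop, fits, f_max=1.0, rho=0.1)
        assert out[0] == pytest.approx(0.65)

    def test_absent_gene_only_decays(self):
        tau = np.array([0.8, 0.8])
        pop = np.array([[1, 0]], dtype=np.uint8)
        out = update_pheromone(tau, pop, np.array([0.5]), f_max=0.5, rho=0.1)
        assert out[1] == pytest.approx(0.9 * 0.8)

    def test_clamped_to_bounds(self):
        tau = np.array([0.98, 0.02])
        pop = np.array([[1, 0]], dtype=np.uint8)
        out = update_pheromone(tau, pop, np.array([1.0]), 1.0, rho=0.5,
                               tau_min=0.01, tau_max=0.99)
        assert out[0] <= 0.99 and out[1] >= 0.01


class TestToggleProbabilities:
    def test_equal_tau_gives_uniform(self):
        probs = toggle_probabilities(np.full(4, 0.3), alpha=1, beta=1)
        np.testing.assert_allclose(probs, 0.25)

    def test_zero_exponents_give_uniform(self):
        probs = toggle_probabilities(np.array([0.1, 0.5, 0.9]), alpha=0, beta=0)
        np.testing.assert_allclose(probs, 1 / 3)

    def test_worked_example(self):
        """tau=(.9,.5), alpha=beta=1 -> (.09,.25)/.34."""
        probs = toggle_probabilities(np.array([0.9, 0.5]), alpha=1, beta=1)
        np.testing.assert_allclose(probs, [0.09 / 0.34, 0.25 / 0.34])

    @given(
        tau=st.lists(st.floats(0.01, 0.99), min_size=1, max_size=30),
        alpha=st.floats(0, 3),
        beta=st.floats(0, 3),
    )
    def test_normalization_property(self, tau, alpha, beta):
        probs = toggle_probabilities(np.array(tau), alpha, beta)
        assert abs(probs.sum() - 1.0) <= 1e-12
        assert (probs >= 0).all()


class TestAntLocalSearch:
    def test_zero_bit_flip_always_accepted_under_popcount(self, small_rng):
        mask = np.array([1, 0, 0, 0], dtype=np.uint8)
        probs = np.array([0.0, 1.0, 0.0, 0.0])  # force the 0-bit at index 1
        new, f, cand = ant_local_search(
            mask, popcount_fitness(mask), probs, 1, popcount_fitness, small_rng
        )
        assert f == 2.0 and new[1] == 1
        assert (cand == new).all()

    def test_worse_candidate_keeps_incumbent(self, small_rng):
        mask = np.array([1, 1, 0], dtype=np.uint8)
        probs = np.array([1.0, 0.0, 0.0])  # force removal: popcount drops
        new, f, cand = ant_local_search(
            mask, popcount_fitness(mask), probs, 1, popcount_fitness, small_rng
        )
        assert (new == mask).all() and f == 2.0
        assert cand[0] == 0  # the rejected proposal is still reported

    def test_fitness_never_decreases(self, small_rng):
        mask = np.array([0, 1, 1, 0, 1], dtype=np.uint8)
        probs = np.full(5, 0.2)
        f0 = popcount_fitness(mask)
        for _ in range(20):
            mask, f0, _ = ant_local_search(mask, f0, probs, 2, popcount_fitness, small_rng)
            assert f0 >= popcount_fitness(mask) - 1e-12


class TestLevyStep:
    def test_deterministic_and_linear_in_step_size(self):
        a = levy_step(50, s=0.1, sigma=1.0, rng=np.random.default_rng(4))
        b = levy_step(50, s=0.1, sigma=1.0, rng=np.random.default_rng(4))
        c = levy_step(50, s=0.2, sigma=1.0, rng=np.random.default_rng(4))
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(c, 2 * a)

    def test_heavy_tail_witness(self):
        steps = np.abs(levy_step(100_000, s=1.0, sigma=1.0, rng=np.random.default_rng(6)))
        assert np.quantile(steps, 0.999) > 20 * np.median(steps)

    def test_signs_are_balanced(self):
        steps = levy_step(100_000, s=1.0, sigma=1.0, rng=np.random.default_rng(7))
        assert abs(np.mean(steps > 0) - 0.5) < 0.01


class TestGrasshopperMove:
    def test_zero_step_is_identity_candidate(self, small_rng):
        mask = np.array([1, 0, 1], dtype=np.uint8)
        new, f, cand = grasshopper_move(
            mask, popcount_fitness(mask), np.zeros(3), 0.5, popcount_fitness, small_rng
        )
        assert (cand == mask).all() and (new == mask).all()

    def test_threshold_binarization(self, small_rng):
        """Component .7 with T=.5 -> bit 1; component .3 -> bit 0."""
        mask = np.zeros(2, dtype=np.uint8)
        step = np.array([0.7, 0.3])
        _, _, cand = grasshopper_move(
            mask, popcount_fitness(mask), step, 0.5, popcount_fitness, small_rng
        )
        assert cand.tolist() == [1, 0]

    def test_greedy_acceptance_never_decreases_fitness(self, small_rng):
        mask = np.array([1, 1, 0, 0], dtype=np.uint8)
        f0 = popcount_fitness(mask)
        for _ in range(20):
            step = levy_step(4, 0.5, 1.0, small_rng)
            mask, f0, _ = grasshopper_move(mask, f0, step, 0.5, popcount_fitness, small_rng)
        assert f0 >= 2.0


class TestSuccessScoresAndWeights:
    def test_single_individual_at_peak_returns_its_mask(self):
        pop = np.array([[1, 0, 1]], dtype=np.uint8)
        s_a, s_g = success_scores(pop, np.array([0.7]), np.array([0.7]), f_max=0.7)
        np.testing.assert_allclose(s_a, pop[0])

    def test_unselected_gene_scores_zero(self):
        pop = np.array([[1, 0], [1, 0]], dtype=np.uint8)
        s_a, _ = success_scores(pop, np.array([1.0, 1.0]), np.array([1.0, 1.0]), 1.0)
        assert s_a[1] == 0.0

    def test_worked_example(self):
        """Ratios (1.0, .5) with masks (1,0) and (1,1) -> S = (1.5, .5)."""
        pop = np.array([[1, 0], [1, 1]], dtype=np.uint8)
        s_a, _ = success_scores(pop, np.array([1.0, 0.5]), np.array([0.0, 0.0]), 1.0)
        np.testing.assert_allclose(s_a, [1.5, 0.5])

    def test_nonpositive_peak_zeroes_scores(self):
        pop = np.ones((2, 3), dtype=np.uint8)
        s_a, s_g = success_scores(pop, np.array([-1.0, -2.0]), np.array([-1.0, -2.0]), -1.0)
        assert not s_a.any() and not s_g.any()

    @pytest.mark.parametrize(
        "s_a, s_g, expect",
        [
            (np.array([1.0, 1.0]), np.array([2.0, 0.0]), (0.5, 0.5)),
            (np.array([0.0, 0.0]), np.array([3.0, 1.0]), (0.0, 1.0)),
            (np.array([3.0]), np.array([1.0]), (0.75, 0.25)),
            (np.zeros(2), np.zeros(2), (0.5, 0.5)),
        ],
    )
    def test_adaptive_weights(self, s_a, s_g, expect):
        w_a, w_g = adaptive_weights(s_a, s_g)
        assert (w_a, w_g) == pytest.approx(expect)
        assert w_a + w_g == pytest.approx(1.0)


class TestComprehensiveUpdate:
    def test_full_ant_weight_recovers_ant_proposal(self, small_rng):
        """W_A=1: the blended, thresholded mask is exactly the ant candidate."""
        pop = np.array([[1, 0, 0, 1, 0]], dtype=np.uint8)
        ant = np.array([[1, 1, 0, 1, 0]], dtype=np.uint8)
        grass = pop.copy()
        new_pop, new_fit = comprehensive_update(
            pop, np.array([2.0]), ant, grass, 1.0, 0.0, 0.5, popcount_fitness, small_rng
        )
        assert (new_pop[0] == ant[0]).all()
        assert new_fit[0] == 3.0

    def test_identical_proposals_are_a_fixed_point(self, small_rng):
        pop = np.array([[1, 0, 1]], dtype=np.uint8)
        new_pop, new_fit = comprehensive_update(
            pop, np.array([2.0]), pop.copy(), pop.copy(), 0.6, 0.4, 0.5,
            popcount_fitness, small_rng,
        )
        assert (new_pop == pop).all() and new_fit[0] == 2.0

    def test_output_masks_binary_and_non_empty(self, small_rng):
        rng = np.random.default_rng(8)
        pop = rng.integers(0, 2, (6, 10)).astype(np.uint8)
        pop[pop.sum(axis=1) == 0, 0] = 1
        ant = rng.integers(0, 2, (6, 10)).astype(np.uint8)
        grass = rng.integers(0, 2, (6, 10)).astype(np.uint8)
        fits = pop.sum(axis=1).astype(float)
        new_pop, _ = comprehensive_update(
            pop, fits, ant, grass, 0.55, 0.45, 0.5, popcount_fitness, small_rng
        )
        assert np.isin(new_pop, (0, 1)).all()
        assert (new_pop.sum(axis=1) > 0).all()


def brute_force_optimum(fitness_fn, n_genes):
    """Independent oracle: enumerate every non-empty mask."""
    best = -np.inf
    for bits in itertools.product((0, 1), repeat=n_genes):
        if any(bits):
            best = max(best, fitness_fn(np.array(bits, dtype=np.uint8)))
    return best


class TestOptimize:
    def surrogate(self, n_genes=8, seed=99):
        rng = np.random.default_rng(seed)
        gains = np.where(np.arange(n_genes) % 3 == 0, 1.0, -0.4)
        q = rng.normal(0, 0.1, (n_genes, n_genes))
        q = (q + q.T) / 2
        np.fill_diagonal(q, 0.0)

        def f(mask):
            m = mask.astype(float)
            return float(m @ gains + 0.5 * m @ q @ m)

        return f

    def test_trace_length_and_monotone_best(self):
        f = self.surrogate()
        params = CLBSOParams(population_size=8, max_iterations=25, seed=3)
        _, best, trace = optimize(f, 8, params)
        assert len(trace) == 25
        fits = [r.best_fitness for r in trace]
        assert all(b >= a for a, b in zip(fits, fits[1:]))
        assert best == fits[-1]

    def test_never_exceeds_exhaustive_optimum(self):
        f = self.surrogate()
        oracle = brute_force_optimum(f, 8)
        params = CLBSOParams(population_size=10, max_iterations=40, seed=1)
        _, best, _ = optimize(f, 8, params)
        assert best <= oracle + 1e-12

    def test_identical_seed_identical_result(self):
        f = self.surrogate()
        params = CLBSOParams(population_size=8, max_iterations=15, seed=11)
        m1, b1, t1 = optimize(f, 8, params)
        m2, b2, t2 = optimize(f, 8, params)
        assert (m1 == m2).all() and b1 == b2
        # NaN-tolerant record comparison (surrogates report no accuracy)
        np.testing.assert_equal(
            [dataclasses.asdict(r) for r in t1], [dataclasses.asdict(r) for r in t2]
        )

    def test_ablation_flag_skips_learning_phase(self):
        f = self.surrogate()
        params = CLBSOParams(
            population_size=8, max_iterations=10, seed=2, comprehensive_learning=False
        )
        _, _, trace = optimize(f, 8, params)
        assert all(np.isnan(r.w_ant) for r in trace)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CLBSOParams(population_size=1).validate()
        with pytest.raises(ValueError):
            CLBSOParams(init_prob=0.0).validate()
        with pytest.raises(ValueError):
            CLBSOParams(tau_min=0.5, tau_max=0.4).validate()


@pytest.fixture(scope="module")
def tiny_result(tiny_dataset):
    params = CLBSOParams(population_size=5, max_iterations=6, seed=4)
    return run_clbso(tiny_dataset, "nb", params, cv_folds=3)


class TestRunClbso:

    def test_selected_genes_match_mask(self, tiny_result, tiny_dataset):
        sel = tiny_dataset.gene_ids[tiny_result.best_mask.astype(bool)]
        assert list(sel) == tiny_result.selected_genes
        assert 1 <= len(sel) <= tiny_dataset.n_genes

    def test_trace_accuracy_populated(self, tiny_result):
        assert len(tiny_result.trace) == 6
        assert all(0 <= r.best_accuracy <= 1 for r in tiny_result.trace)

    def test_reproducible(self, tiny_dataset, tiny_result):
        params = CLBSOParams(population_size=5, max_iterations=6, seed=4)
        again = run_clbso(tiny_dataset, "nb", params, cv_folds=3)
        assert (again.best_mask == tiny_result.best_mask).all()
        assert again.best_fitness == tiny_result.best_fitness
        assert again.trace == tiny_result.trace

    def test_fixed_data_seed_shares_split(self, tiny_dataset):
        params = CLBSOParams(population_size=4, max_iterations=2, seed=1)
        a = run_clbso(tiny_dataset, "nb", params, cv_folds=3, data_seed=123)
        b = run_clbso(
            tiny_dataset, "nb", dataclasses.replace(params, seed=2),
            cv_folds=3, data_seed=123,
        )
        assert (a.split.roles == b.split.roles).all()
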