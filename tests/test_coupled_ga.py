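"""Coupled GA: zero-sum coupling, memory filter, best response, determinism."""

import itertools

import numpy as np
import pytest

from metatempo.coupled_ga import (
    BitPopulation,
    ExtinctionEvent,
    GAParams,
    GameSpec,
    best_response,
    coupled_fitness,
    memory_update,
    run_coevolution,
    step_generation,
)
from metatempo.envstreams import ValidationError


def make_pop(genomes, role="prey"):
    genomes = np.asarray(genomes, dtype=np.uint8)
    return BitPopulation(genomes=genomes, filtered_fitness=np.full(len(genomes), 0.5), role=role)


class TestCoupledFitness:
    def test_perfect_match_and_zero_sum_complement(self, rng):
        ones = make_pop(np.ones((8, 4)), role="prey")
        predator_genome = np.ones(4, dtype=np.uint8)
        assert coupled_fitness(predator_genome, "predator", ones, GameSpec(), 8, rng) == 1.0
        prey_pop = make_pop(np.ones((8, 4)), role="predator")
        assert coupled_fitness(np.ones(4, dtype=np.uint8), "prey", prey_pop, GameSpec(), 8, rng) == 0.0

    def test_random_opponents_give_half_matching(self, rng):
        opposing = make_pop(rng.integers(0, 2, size=(256, 8)), role="prey")
        genome = rng.integers(0, 2, size=8).astype(np.uint8)
        fit = coupled_fitness(genome, "predator", opposing, GameSpec(), 256, rng)
        se = np.sqrt(0.25 / (256 * 8))
        assert abs(fit - 0.5) <= 3 * se

    def test_zero_sum_closure_is_exact(self, rng):
        game = GameSpec()
        for _ in range(20):
            a = rng.integers(0, 2, size=10).astype(np.uint8)
            b = rng.integers(0, 2, size=(1, 10)).astype(np.uint8)
            assert game.payoff(a, b, "predator") + game.payoff(a, b, "prey") == 1.0

    def test_extinct_opponent_raises(self, rng):
        empty = BitPopulation(genomes=np.empty((0, 4), dtype=np.uint8), filtered_fitness=np.empty(0), role="prey")
        with pytest.raises(ExtinctionEvent):
            coupled_fitness(np.ones(4, dtype=np.uint8), "predator", empty, GameSpec(), 1, rng)


class TestMemory:
    def test_memoryless_reduction(self):
        assert memory_update(0.3, 0.9, 0.0) == 0.9

    def test_constant_input_is_fixed_point(self):
        f = 0.6
        assert memory_update(f, f, 0.7) == pytest.approx(f)

    def test_hand_recursion(self):
        filtered = 0.0
        out = []
        for inst in (1.0, 0.0, 0.0):
            filtered = memory_update(filtered, inst, 0.5)
            out.append(filtered)
        assert out == [0.5, 0.25, 0.125]

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValidationError):
            memory_update(0.5, 0.5, 1.0)


class TestGeneration:
    def test_clonal_populations_without_operators_are_stable(self, rng):
        params = GAParams(genome_length=6, pop_size=8, mutation_rate=0.0, crossover_rate=0.0)
        pred = make_pop(np.tile([1, 0, 1, 0, 1, 0], (8, 1)), role="predator")
        prey = make_pop(np.tile([0, 1, 0, 1, 0, 1], (8, 1)), role="prey")
        new_pred, new_prey, stats = step_generation(pred, prey, params, GameSpec(), rng)
        assert (new_pred.genomes == pred.genomes[0]).all()
        assert (new_prey.genomes == prey.genomes[0]).all()
        assert stats["meanfit_pred"] == 0.0  # perfectly mismatched clones
        assert stats["meanfit_prey"] == 1.0

    def test_low_fitness_population_gets_minority_share(self, rng):
        params = GAParams(genome_length=4, pop_size=16, repro_exponent=1.0)
        # prey matching predators on 3 of 4 bits: prey fitness 0.25 vs 0.75
        pred = make_pop(np.ones((16, 4)), role="predator")
        prey_genomes = np.ones((16, 4))
        prey_genomes[:, 0] = 0
        prey = make_pop(prey_genomes, role="prey")
        _, _, stats = step_generation(pred, prey, params, GameSpec(), rng)
        assert stats["size_prey"] < params.pop_size
        assert stats["size_pred"] + stats["size_prey"] == 2 * params.pop_size

    def test_fitness_zero_share_is_an_extinction_event(self, rng):
        params = GAParams(genome_length=4, pop_size=8, repro_exponent=1.0)
        # prey identical to predators: predators always match -> prey fitness 0
        pred = make_pop(np.ones((8, 4)), role="predator")
        prey = make_pop(np.ones((8, 4)), role="prey")
        with pytest.raises(ExtinctionEvent) as err:
            step_generation(pred, prey, params, GameSpec(), rng)
        assert err.value.role == "prey"

    def test_no_variation_operators_create_no_new_genomes(self, rng):
        """Without mutation and crossover the distinct-genome set only shrinks
        (resampling can re-weight it, so pairwise diversity may fluctuate)."""
        params = GAParams(genome_length=8, pop_size=16, mutation_rate=0.0, crossover_rate=0.0)
        pred = make_pop(rng.integers(0, 2, (16, 8)), role="predator")
        prey = make_pop(rng.integers(0, 2, (16, 8)), role="prey")
        for _ in range(10):
            seen_pred = {g.tobytes() for g in pred.genomes}
            seen_prey = {g.tobytes() for g in prey.genomes}
            pred, prey, _ = step_generation(pred, prey, params, GameSpec(), rng)
            assert {g.tobytes() for g in pred.genomes} <= seen_pred
            assert {g.tobytes() for g in prey.genomes} <= seen_prey


class TestRuns:
    def test_full_run_is_seed_deterministic(self):
        params = GAParams(generations=30)
        s1, o1, p1, q1 = run_coevolution(params, seed=5)
        s2, o2, p2, q2 = run_coevolution(params, seed=5)
        assert s1.equals(s2)
        assert (p1.genomes == p2.genomes).all()
        assert (q1.genomes == q2.genomes).all()
        assert o1 == o2

    def test_memoryless_filtered_equals_instantaneous(self):
        series, _, _, _ = run_coevolution(GAParams(memory_lambda=0.0, generations=40), seed=2)
        assert np.allclose(series["filtered_pred"], series["meanfit_pred"])
        assert np.allclose(series["filtered_prey"], series["meanfit_prey"])

    def test_kappa_survival_over_long_run(self):
        survived = 0
        for seed in range(10):
            _, outcome, _, _ = run_coevolution(
                GAParams(repro_exponent=1.0, generations=500), seed=seed
            )
            survived += outcome["status"] == "completed"
        assert survived >= 9

    def test_frozen_opponent_recovers_exhaustive_best_response(self):
        """Evolving side converges to the brute-force optimum (2^8 enumeration)."""
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            # clonal frozen opponent with one random target genome
            target = rng.integers(0, 2, 8, dtype=np.uint8)
            prey = BitPopulation(
                genomes=np.tile(target, (64, 1)),
                filtered_fitness=np.full(64, 0.5),
                role="prey",
            )
            params = GAParams(pop_size=64, generations=60, seed=seed)
            _, _, pred, _ = run_coevolution(params, seed=seed, freeze="prey", init_prey=prey)
            # independent oracle: enumerate all 2^8 candidate genomes
            best, best_fit = None, -1.0
            for bits in itertools.product([0, 1], repeat=8):
                cand = np.array(bits, dtype=np.uint8)
                fit = float((cand[None, :] == prey.genomes).mean())
                if fit > best_fit:
                    best, best_fit = cand, fit
            vals, counts = np.unique(pred.genomes, axis=0, return_counts=True)
            modal = vals[np.argmax(counts)]
            hits += np.array_equal(modal, best)
            assert np.array_equal(best_response(prey, "predator"), best)
        assert hits >= n_seeds - 1

    def test_red_queen_cycling_at_default_config(self):
        cycling = 0
        for seed in range(5):
            series, outcome, _, _ = run_coevolution(GAParams(), seed=seed)
            assert outcome["status"] == "completed"
            std = float(series["meanfit_pred"].iloc[len(series) // 2 :].std())
            cycling += std > 0.05
        assert cycling >= 4

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            GAParams(mutation_rate=1.5)
        with pytest.raises(ValidationError):
            GAParams(memory_lambda=1.0)
        with pytest.raises(ValidationError):
            GAParams(lifetime_samples=0)
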