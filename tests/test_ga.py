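"""GA operators and the evolutionary loop."""

import numpy as np
import pytest

from emdav.encoding import EncodingSpec, Genome, decode, random_genome
from emdav.ga import (GAConfig, evolve, linear_rank_select, mutate,
                      rank_probabilities, run_emdav, uniform_crossover)
from emdav.nn import FitnessRecord

SMALL = EncodingSpec(n_feature_bits=5, layer_field_bits=2, node_field_bits=1)


def bitcount_fitness(genome, seed):
    return FitnessRecord("surrogate", "holdout",
                         [float(genome.bits.sum())], [0.0], 1)


# -- selection ---------------------------------------------------------------

def test_rank_probabilities_n2_sp2():
    np.testing.assert_allclose(rank_probabilities(2, 2.0), [1.0, 0.0])


def test_rank_probabilities_sum_to_one():
    for n in (3, 10, 50):
        for sp in (1.0, 1.5, 2.0):
            assert rank_probabilities(n, sp).sum() == pytest.approx(1.0)


def test_selection_prefers_better_fitness(rng):
    fits = np.array([0.5, 0.1, 0.9, 0.3])  # best is index 1, worst index 2
    picks = linear_rank_select(fits, 10_000, rng, pressure=1.5)
    counts = np.bincount(picks, minlength=4)
    assert counts[1] > counts[3] > counts[0] > counts[2]
    assert counts[2] > 0  # SP < 2 keeps the worst alive


def test_selection_uniform_when_fitnesses_equal(rng):
    picks = linear_rank_select(np.ones(4), 10_000, rng, pressure=2.0)
    counts = np.bincount(picks, minlength=4)
    # symmetric case: all frequencies within binomial tolerance of 1/4
    assert np.all(np.abs(counts / 10_000 - 0.25) < 0.02)


def test_selection_errors():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        linear_rank_select(np.array([]), 2, rng)
    with pytest.raises(ValueError):
        linear_rank_select(np.ones(3), 1, rng)


# -- crossover ---------------------------------------------------------------

def test_identical_parents_give_identical_children(rng):
    g = random_genome(SMALL, rng)
    c1, c2 = uniform_crossover(g, g, 1.0, rng)
    np.testing.assert_array_equal(c1.bits, g.bits)
    np.testing.assert_array_equal(c2.bits, g.bits)


def test_crossover_conserves_alleles_positionwise(rng):
    for _ in range(50):
        p1, p2 = random_genome(SMALL, rng), random_genome(SMALL, rng)
        c1, c2 = uniform_crossover(p1, p2, 1.0, rng)
        np.testing.assert_array_equal(np.sort(np.stack([c1.bits, c2.bits]), axis=0),
                                      np.sort(np.stack([p1.bits, p2.bits]), axis=0))


def test_crossover_probability_zero_clones(rng):
    p1, p2 = random_genome(SMALL, rng), random_genome(SMALL, rng)
    c1, c2 = uniform_crossover(p1, p2, 0.0, rng)
    np.testing.assert_array_equal(c1.bits, p1.bits)
    np.testing.assert_array_equal(c2.bits, p2.bits)


def test_crossover_inheritance_is_balanced():
    rng = np.random.default_rng(3)
    p1 = Genome(np.zeros(SMALL.total_length, np.uint8), SMALL)
    p2 = Genome(np.ones(SMALL.total_length, np.uint8), SMALL)
    from_p2 = np.zeros(SMALL.total_length)
    n = 10_000
    for _ in range(n):
        c1, _ = uniform_crossover(p1, p2, 1.0, rng)
        from_p2 += c1.bits
    assert np.all(np.abs(from_p2 / n - 0.5) < 0.02)


# -- mutation ----------------------------------------------------------------

def test_mutation_probability_zero_is_identity(rng):
    g = random_genome(SMALL, rng)
    np.testing.assert_array_equal(mutate(g, 0.0, rng).bits, g.bits)


def test_per_bit_rate_one_is_complement(rng):
    g = random_genome(SMALL, rng)
    out = mutate(g, 1.0, rng, mode="per_bit")
    np.testing.assert_array_equal(out.bits, 1 - g.bits)


def test_per_individual_mean_flip_rate(rng):
    g = Genome(np.zeros(SMALL.total_length, np.uint8), SMALL)
    n = 10_000
    flips = sum(int(mutate(g, 0.1, rng).bits.sum()) for _ in range(n))
    # expected flips per call = 0.1 * L * (1/L) = 0.1
    se = np.sqrt(0.1 / n)
    assert abs(flips / n - 0.1) < 3 * se + 0.01


# -- evolution ---------------------------------------------------------------

def test_evolve_smoke_and_monotone_best():
    cfg = GAConfig(population_size=4, max_generations=2, stall_generations=10,
                   cache_on_active_region=False, seed=0)
    res = evolve(None, cfg, None, SMALL, fitness_fn=bitcount_fitness)
    assert len(res.generations) == 2
    trace = res.best_fitness_trace
    assert all(b <= a for a, b in zip(trace, trace[1:]))
    assert res.n_evaluations <= 8
    assert {r["generation"] for r in res.individuals} == {0, 1}


def test_population_size_constant_across_generations():
    cfg = GAConfig(population_size=7, max_generations=4, stall_generations=10,
                   cache_on_active_region=False, seed=1)
    res = evolve(None, cfg, None, SMALL, fitness_fn=bitcount_fitness)
    for g in range(4):
        assert sum(r["generation"] == g for r in res.individuals) == 7


def test_no_variation_converges_to_elite_copies():
    cfg = GAConfig(population_size=10, crossover_prob=0.0, mutation_prob=0.0,
                   max_generations=15, stall_generations=50,
                   cache_on_active_region=False, seed=2)
    res = evolve(None, cfg, None, SMALL, fitness_fn=bitcount_fitness)
    last_gen = max(r["generation"] for r in res.individuals)
    genomes = {r["genome"] for r in res.individuals if r["generation"] == last_gen}
    assert len(genomes) <= cfg.n_elites


def test_evaluation_budget_aborts_gracefully():
    cfg = GAConfig(population_size=10, max_generations=50, stall_generations=50,
                   max_evaluations=25, cache_on_active_region=False, seed=3)
    res = evolve(None, cfg, None, SMALL, fitness_fn=bitcount_fitness)
    assert res.termination_reason == "evaluation_budget"
    assert res.n_evaluations <= 25
    assert res.best_record is not None


def test_stall_terminates_on_flat_fitness():
    def constant_fitness(genome, seed):
        return FitnessRecord("s", "holdout", [1.0], [0.0], 1)
    cfg = GAConfig(population_size=5, max_generations=50, stall_generations=3,
                   cache_on_active_region=False, seed=4)
    res = evolve(None, cfg, None, SMALL, fitness_fn=constant_fitness)
    assert res.termination_reason == "stall"
    # baseline generation + 3 consecutive generations without improvement
    assert len(res.generations) == 4


def test_failing_evaluations_use_sentinel_not_abort():
    def flaky(genome, seed):
        if genome.bits[0] == 1:
            return FitnessRecord.infeasible("bad")
        return bitcount_fitness(genome, seed)
    cfg = GAConfig(population_size=6, max_generations=5, stall_generations=10,
                   cache_on_active_region=False, seed=5)
    res = evolve(None, cfg, None, SMALL, fitness_fn=flaky)
    assert len(res.generations) == 5


def test_run_emdav_reproducible_and_sorted():
    cfg = GAConfig(population_size=6, max_generations=3, stall_generations=10,
                   cache_on_active_region=False, seed=11)
    res_a, rep_a = run_emdav(None, cfg, None, SMALL, n_executions=2,
                             fitness_fn=bitcount_fitness)
    res_b, rep_b = run_emdav(None, cfg, None, SMALL, n_executions=2,
                             fitness_fn=bitcount_fitness)
    assert rep_a.equals(rep_b)
    assert list(rep_a["mse"]) == sorted(rep_a["mse"])
    # independent executions use distinct seeds -> generally distinct logs
    assert res_a[0].generations != res_a[1].generations


def test_dataset_feature_count_must_match_encoding(tiny_dataset):
    with pytest.raises(ValueError):
        evolve(tiny_dataset, GAConfig(), None, SMALL, fitness_fn=bitcount_fitness)
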