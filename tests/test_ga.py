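import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpgselect.data import DataError
from cpgselect.fitness import GBRParams
from cpgselect.ga import (
    GAConfig,
    crossover_parent_difference,
    init_population,
    mutate,
    next_generation,
    roulette_select,
    run_all_groups,
    run_ga,
)
from cpgselect.synth import SynthConfig, baseline_mad, generate_cohort

FAST_GBR = GBRParams(n_estimators=25, learning_rate=0.2, seed=0)

bits = st.lists(st.integers(0, 1), min_size=1, max_size=64)


def _small_ga_ds(seed=2):
    cfg = SynthConfig(n_samples=60, n_sites=40, n_informative=4,
                      noise_sd_per_regime=(0.01, 0.01, 0.01), seed=seed)
    return generate_cohort(cfg)


class TestInitPopulation:
    def test_expected_ones_count(self):
        cfg = GAConfig(population_size=100, generations=1, elitism_count=10,
                       chromosome_length=8000, init_density=0.0125, seed=0)
        pop = init_population(cfg)
        mean_ones = np.mean([c.sum() for c in pop])
        # Binomial(8000, 0.0125): mean 100, sd ~9.9; population mean is tighter
        assert 85 <= mean_ones <= 115

    def test_same_seed_identical(self):
        cfg = GAConfig(population_size=5, generations=1, elitism_count=1,
                       chromosome_length=50, init_density=0.1, seed=3)
        a = init_population(cfg)
        b = init_population(cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_all_zero_redrawn(self):
        cfg = GAConfig(population_size=200, generations=1, elitism_count=1,
                       chromosome_length=3, init_density=0.05, seed=1)
        pop = init_population(cfg)
        assert all(c.any() for c in pop)
        assert len(pop) == 200


class TestRouletteSelect:
    def test_equal_fitness_uniform(self):
        rng = np.random.default_rng(0)
        counts = np.zeros(4)
        draws = 10_000
        for _ in range(draws // 2):
            i, j = roulette_select([2.0, 2.0, 2.0, 2.0], rng)
            counts[i] += 1
            counts[j] += 1
        expected = draws / 4
        sd = math.sqrt(draws * 0.25 * 0.75)
        assert np.all(np.abs(counts - expected) < 3 * sd)

    def test_population_of_one(self):
        assert roulette_select([1.5], np.random.default_rng(0)) == (0, 0)

    def test_infinite_fitness_never_selected(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            i, j = roulette_select([1.0, math.inf], rng)
            assert (i, j) == (0, 0)

    def test_all_infinite_uniform_with_warning(self):
        with pytest.warns(UserWarning, match="infinite"):
            i, j = roulette_select([math.inf, math.inf], np.random.default_rng(0))
        assert i in (0, 1) and j in (0, 1)


class TestCrossover:
    def test_paper_example_contract(self):
        p1 = np.array([1, 1, 0, 0], dtype=np.int8)
        p2 = np.array([1, 0, 1, 0], dtype=np.int8)
        c1, c2 = crossover_parent_difference(p1, p2, np.random.default_rng(0))
        assert c1[0] == c2[0] == 1 and c1[3] == c2[3] == 0
        assert c2[1] == 1 - c1[1] and c2[2] == 1 - c1[2]

    def test_identical_parents_cloned(self):
        p = np.array([1, 0, 1, 1], dtype=np.int8)
        c1, c2 = crossover_parent_difference(p, p, np.random.default_rng(0))
        np.testing.assert_array_equal(c1, p)
        np.testing.assert_array_equal(c2, p)

    def test_length_mismatch_errors(self):
        with pytest.raises(DataError):
            crossover_parent_difference(np.zeros(3), np.zeros(4), 0)

    @settings(max_examples=50, deadline=None)
    @given(bits, bits, st.integers(0, 2**32 - 1))
    def test_xor_and_agreement_invariants(self, b1, b2, seed):
        n = min(len(b1), len(b2))
        p1 = np.array(b1[:n], dtype=np.int8)
        p2 = np.array(b2[:n], dtype=np.int8)
        c1, c2 = crossover_parent_difference(p1, p2, seed)
        np.testing.assert_array_equal(c1 ^ c2, p1 ^ p2)
        agree = p1 == p2
        np.testing.assert_array_equal(c1[agree], p1[agree])
        np.testing.assert_array_equal(c2[agree], p1[agree])
        assert c1.sum() + c2.sum() == p1.sum() + p2.sum()


class TestMutate:
    def test_hamming_distance_exactly_k(self):
        rng = np.random.default_rng(0)
        chrom = (rng.random(200) < 0.3).astype(np.int8)
        out = mutate(chrom, 4, rng)
        assert int((out != chrom).sum()) == 4

    def test_k_zero_identity(self):
        chrom = np.array([1, 0, 1], dtype=np.int8)
        np.testing.assert_array_equal(mutate(chrom, 0, 0), chrom)

    def test_empty_pool_fallback(self):
        chrom = np.zeros(10, dtype=np.int8)
        out = mutate(chrom, 2, np.random.default_rng(0))
        assert out.sum() == 2  # both flips forced 0 -> 1

    def test_k_capped_at_length(self):
        chrom = np.array([1, 0], dtype=np.int8)
        out = mutate(chrom, 10, 0)
        np.testing.assert_array_equal(out, 1 - chrom)

    @settings(max_examples=40, deadline=None)
    @given(bits, st.integers(0, 8), st.integers(0, 2**32 - 1))
    def test_flip_count_property(self, b, k, seed):
        chrom = np.array(b, dtype=np.int8)
        out = mutate(chrom, k, seed)
        assert int((out != chrom).sum()) == min(k, len(b))

    def test_balanced_pool_choice(self):
        # with both pools large, ~half of flips hit the 1-pool
        rng = np.random.default_rng(7)
        chrom = (np.arange(400) < 200).astype(np.int8)
        one_flips = total = 0
        for _ in range(2000):
            out = mutate(chrom, 5, rng)
            one_flips += int(((chrom == 1) & (out == 0)).sum())
            total += 5
        assert abs(one_flips / total - 0.5) < 0.02


class TestNextGeneration:
    def _pop(self, n=10, length=30, seed=0):
        rng = np.random.default_rng(seed)
        return [(rng.random(length) < 0.3).astype(np.int8) for _ in range(n)]

    def test_size_preserved_and_elites_copied(self):
        pop = self._pop()
        fits = list(np.linspace(1, 10, 10))
        cfg = GAConfig(population_size=10, generations=1, elitism_count=3,
                       mutation_k=2, chromosome_length=30, init_density=0.3, seed=0)
        out = next_generation(pop, fits, cfg, 0)
        assert len(out) == 10
        for e, src in zip(out[:3], pop[:3]):  # fits already sorted ascending
            np.testing.assert_array_equal(e, src)

    def test_elite_ties_to_lower_index(self):
        pop = self._pop(4)
        cfg = GAConfig(population_size=4, generations=1, elitism_count=1,
                       mutation_k=1, chromosome_length=30, init_density=0.3, seed=0)
        out = next_generation(pop, [5.0, 5.0, 5.0, 5.0], cfg, 0)
        np.testing.assert_array_equal(out[0], pop[0])


class TestRunGa:
    def test_history_and_contracts(self):
        ds, _ = _small_ga_ds()
        cfg = GAConfig(population_size=8, generations=4, elitism_count=2,
                       mutation_k=3, chromosome_length=40, init_density=0.1, seed=5)
        best, hist = run_ga(ds, cfg, FAST_GBR, target_size=30)
        assert len(hist) == 4
        # elitism monotonicity
        assert all(b2 <= b1 + 1e-12 for b1, b2 in
                   zip(hist.best_fitness, hist.best_fitness[1:]))
        assert best.shape == (40,)

    def test_parallel_degree_equivalence(self):
        ds, _ = _small_ga_ds()
        cfg = GAConfig(population_size=6, generations=3, elitism_count=2,
                       mutation_k=3, chromosome_length=40, init_density=0.1, seed=6)
        b1, h1 = run_ga(ds, cfg, FAST_GBR, target_size=30, parallelism_degree=1)
        b4, h4 = run_ga(ds, cfg, FAST_GBR, target_size=30, parallelism_degree=4)
        np.testing.assert_array_equal(b1, b4)
        assert h1.best_fitness == h4.best_fitness
        assert h1.avg_fitness == h4.avg_fitness

    def test_beats_mean_prediction(self):
        ds, _ = _small_ga_ds(seed=3)
        cfg = GAConfig(population_size=10, generations=5, elitism_count=2,
                       mutation_k=3, chromosome_length=40, init_density=0.1, seed=1)
        _, hist = run_ga(ds, cfg, FAST_GBR, target_size=60)
        penalty = 40 / 50  # even an all-ones chromosome only pays this
        assert hist.best_fitness[-1] < baseline_mad(ds) + penalty

    def test_length_mismatch_errors(self):
        ds, _ = _small_ga_ds()
        cfg = GAConfig(population_size=4, generations=2, elitism_count=1,
                       chromosome_length=99, init_density=0.1, seed=0)
        with pytest.raises(DataError, match="chromosome_length"):
            run_ga(ds, cfg, FAST_GBR)


class TestRunAllGroups:
    def test_three_groups_three_results(self):
        datasets = {g: _small_ga_ds(seed=g)[0] for g in (1, 2, 3)}
        cfg = GAConfig(population_size=4, generations=2, elitism_count=1,
                       mutation_k=2, chromosome_length=40, init_density=0.1, seed=9)
        out = run_all_groups(datasets, cfg, FAST_GBR, target_size=60)
        assert set(out) == {1, 2, 3}
        for best, hist in out.values():
            assert len(hist) == 2

    def test_empty_errors(self):
        with pytest.raises(DataError):
            run_all_groups({}, GAConfig(), FAST_GBR)

    def test_failure_reported_per_group(self):
        good, _ = _small_ga_ds()
        bad = good.select_samples(range(3))  # too few samples
        cfg = GAConfig(population_size=4, generations=2, elitism_count=1,
                       mutation_k=2, chromosome_length=40, init_density=0.1, seed=0)
        with pytest.raises(RuntimeError, match="group 2"):
            run_all_groups({1: good, 2: bad}, cfg, FAST_GBR, target_size=60)
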