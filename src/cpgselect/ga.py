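"""Generational genetic algorithm over binary CpG-selection chromosomes.

Operators are the problem-specific variants: roulette-wheel selection with
inverse-fitness weights (the fitness is minimized), agreement-preserving
crossover whose second child complements the first at every disagreeing
locus, and a balanced k-flip mutation that picks the 1-pool or the 0-pool
with equal probability at each of its k steps.  The best chromosomes of
each generation survive unchanged (elitism), so the best fitness trajectory
is non-increasing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import DataError, MethylationDataset
from .fitness import FitnessRecord, GBRParams, evaluate_population, plan_partitions

__all__ = [
    "Chromosome",
    "GAConfig",
    "GAHistory",
    "init_population",
    "roulette_select",
    "crossover_parent_difference",
    "mutate",
    "next_generation",
    "run_ga",
    "run_all_groups",
]

#: a chromosome is a fixed-length 0/1 gene vector over the filtered CpG panel
Chromosome = np.ndarray

_ROULETTE_EPS = 1e-9


@dataclass
class GAConfig:
    """Population-level GA parameters (reference defaults: 100x100, top-10
    elitism over 8000-gene chromosomes)."""

    population_size: int = 100
    generations: int = 100
    elitism_count: int = 10
    mutation_k: int = 20
    chromosome_length: int = 8000
    init_density: float = 0.0125
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 1 or self.generations < 1:
            raise DataError("population_size and generations must be positive")
        if not 0 <= self.elitism_count < self.population_size:
            raise DataError("elitism_count must lie in [0, population_size)")
        if self.mutation_k < 0 or self.chromosome_length < 1:
            raise DataError("mutation_k must be >= 0 and chromosome_length >= 1")
        if not 0 < self.init_density < 1:
            raise DataError("init_density must lie in (0, 1)")


@dataclass
class GAHistory:
    """Per-generation convergence log."""

    best_fitness: list[float] = field(default_factory=list)
    avg_fitness: list[float] = field(default_factory=list)
    worst_fitness: list[float] = field(default_factory=list)
    best_chromosome: list[Chromosome] = field(default_factory=list)

    def log(self, population: Sequence[Chromosome], fitnesses: Sequence[float]) -> None:
        finite = [f for f in fitnesses if math.isfinite(f)]
        best_idx = min(range(len(fitnesses)), key=lambda i: (fitnesses[i], i))
        self.best_fitness.append(float(fitnesses[best_idx]))
        self.avg_fitness.append(float(np.mean(finite)) if finite else math.inf)
        self.worst_fitness.append(float(max(finite)) if finite else math.inf)
        self.best_chromosome.append(population[best_idx].copy())

    def __len__(self) -> int:
        return len(self.best_fitness)


def _as_rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def init_population(config: GAConfig, rng: np.random.Generator | None = None) -> list[Chromosome]:
    """Bernoulli(init_density) chromosomes; all-zero draws are re-drawn."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    population: list[Chromosome] = []
    while len(population) < config.population_size:
        genes = (rng.random(config.chromosome_length) < config.init_density).astype(np.int8)
        if genes.any():
            population.append(genes)
    return population


def roulette_select(
    fitnesses: Sequence[float], seed: int | np.random.Generator = 0
) -> tuple[int, int]:
    """Two independent roulette draws with weights 1/(fitness + eps).

    Lower (better) fitness gets proportionally more weight; infinite
    fitnesses get zero weight.  If every fitness is infinite the draw falls
    back to uniform with a warning.
    """
    rng = _as_rng(seed)
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise DataError("roulette selection needs a non-empty population")
    weights = np.where(np.isfinite(f), 1.0 / (f + _ROULETTE_EPS), 0.0)
    total = weights.sum()
    if total <= 0:
        warnings.warn("all fitnesses are infinite; selecting uniformly")
        weights = np.ones_like(f)
        total = weights.sum()
    p = weights / total
    i = int(rng.choice(f.size, p=p))
    j = int(rng.choice(f.size, p=p))
    return i, j


def crossover_parent_difference(
    p1: Chromosome, p2: Chromosome, seed: int | np.random.Generator = 0
) -> tuple[Chromosome, Chromosome]:
    """Agreement-preserving crossover.

    Where the parents agree both children copy the shared value; where they
    differ, child 1 takes a fair coin flip and child 2 takes the complement.
    Consequently ``c1 XOR c2 == p1 XOR p2``.
    """
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape:
        raise DataError("parents must have equal length")
    rng = _as_rng(seed)
    coin = rng.integers(0, 2, size=p1.shape, dtype=np.int8)
    agree = p1 == p2
    c1 = np.where(agree, p1, coin).astype(np.int8)
    c2 = np.where(agree, p1, 1 - coin).astype(np.int8)
    return c1, c2


def mutate(chromosome: Chromosome, k: int, seed: int | np.random.Generator = 0) -> Chromosome:
    """Flip exactly ``min(k, length)`` distinct genes, pool-balanced.

    Each of the k steps first picks the 1-pool or the 0-pool with equal
    probability (falling back to the other pool when one is empty), then
    flips a uniformly chosen not-yet-flipped position from that pool.
    """
    chromosome = np.asarray(chromosome)
    rng = _as_rng(seed)
    out = chromosome.astype(np.int8).copy()
    k = min(int(k), out.size)
    flipped = np.zeros(out.size, dtype=bool)
    original = chromosome.astype(np.int8)
    for _ in range(k):
        want = int(rng.integers(0, 2))  # 1 -> pick from the 1-pool
        pool = np.flatnonzero(~flipped & (original == want))
        if pool.size == 0:
            pool = np.flatnonzero(~flipped & (original == 1 - want))
        pos = int(rng.choice(pool))
        out[pos] = 1 - out[pos]
        flipped[pos] = True
    return out


def _rank_indices(fitnesses: Sequence[float]) -> list[int]:
    """Indices sorted by (fitness, index): best first, ties to lower index."""
    return sorted(range(len(fitnesses)), key=lambda i: (fitnesses[i], i))


def next_generation(
    population: Sequence[Chromosome],
    fitnesses: Sequence[float],
    config: GAConfig,
    seed: int | np.random.Generator = 0,
) -> list[Chromosome]:
    """One generational step: elites survive, the rest are bred.

    The ``elitism_count`` best chromosomes are copied unchanged into slots
    0..elitism_count-1; remaining slots are filled by roulette selection,
    crossover and mutation of both children.  The final pair's second child
    is discarded when an odd number of slots remains.
    """
    if len(population) != len(fitnesses):
        raise DataError("one fitness required per chromosome")
    config.validate()
    rng = _as_rng(seed)
    order = _rank_indices(fitnesses)
    elites = [population[i].copy() for i in order[: config.elitism_count]]
    offspring: list[Chromosome] = []
    n_offspring = len(population) - config.elitism_count
    while len(offspring) < n_offspring:
        i, j = roulette_select(fitnesses, rng)
        c1, c2 = crossover_parent_difference(population[i], population[j], rng)
        offspring.append(mutate(c1, config.mutation_k, rng))
        if len(offspring) < n_offspring:
            offspring.append(mutate(c2, config.mutation_k, rng))
    return elites + offspring


def _derive_seed(master: int, *path: int) -> int:
    return int(np.random.SeedSequence([master, *path]).generate_state(1)[0])


def run_ga(
    ds: MethylationDataset,
    ga_config: GAConfig,
    gbr_params: GBRParams,
    parallelism_degree: int = 1,
    target_size: int = 100,
    folds: int = 3,
) -> tuple[Chromosome, GAHistory]:
    """Full GA run on one (filtered) group train set.

    Each generation evaluates the population via the map/reduce fitness
    engine, logs best/avg/worst fitness, and breeds the next generation.
    Elite chromosomes keep their cached fitness record rather than being
    re-evaluated.  Fully deterministic per seed at any parallelism degree.

    Returns the best chromosome ever seen and the per-generation history.
    """
    ga_config.validate()
    if ds.age is None:
        raise DataError("GA requires a dataset with ages")
    if ga_config.chromosome_length != ds.n_sites:
        raise DataError(
            f"chromosome_length={ga_config.chromosome_length} does not match "
            f"{ds.n_sites} dataset sites"
        )
    if ds.n_samples < 2 * folds:
        raise DataError(f"GA needs at least {2 * folds} samples")
    master = ga_config.seed
    init_rng = np.random.default_rng(_derive_seed(master, 0))
    breed_rng = np.random.default_rng(_derive_seed(master, 1))

    population = init_population(ga_config, init_rng)
    records: list[FitnessRecord | None] = [None] * ga_config.population_size
    history = GAHistory()
    best_chrom: Chromosome | None = None
    best_fit = math.inf

    for gen in range(ga_config.generations):
        plan = plan_partitions(ds.n_samples, target_size=target_size,
                               seed=_derive_seed(master, 2, gen))
        todo = [i for i, r in enumerate(records) if r is None]
        fresh = evaluate_population(
            ds, [population[i] for i in todo], plan, gbr_params,
            parallelism_degree=parallelism_degree, folds=folds,
            chrom_keys=[gen * ga_config.population_size + i for i in todo],
        )
        for i, rec in zip(todo, fresh):
            records[i] = rec
        fitnesses = [r.fitness for r in records]  # type: ignore[union-attr]
        history.log(population, fitnesses)
        gen_best = min(range(len(fitnesses)), key=lambda i: (fitnesses[i], i))
        if fitnesses[gen_best] < best_fit:
            best_fit = fitnesses[gen_best]
            best_chrom = population[gen_best].copy()
        if gen < ga_config.generations - 1:
            elite_idx = _rank_indices(fitnesses)[: ga_config.elitism_count]
            population = next_generation(population, fitnesses, ga_config, breed_rng)
            carried = [records[i] for i in elite_idx]
            records = carried + [None] * (ga_config.population_size - len(carried))
    assert best_chrom is not None
    return best_chrom, history


def run_all_groups(
    group_datasets: Mapping[object, MethylationDataset],
    ga_config: GAConfig,
    gbr_params: GBRParams,
    parallelism_degree: int = 1,
    target_size: int = 100,
    folds: int = 3,
) -> dict[object, tuple[Chromosome, GAHistory]]:
    """Run an independent GA per age group (independent derived seeds).

    Per-group failures are collected and re-raised together, identifying
    every failing group.
    """
    if not group_datasets:
        raise DataError("run_all_groups requires at least one group")
    results: dict[object, tuple[Chromosome, GAHistory]] = {}
    failures: dict[object, Exception] = {}
    for gi, (label, gds) in enumerate(group_datasets.items()):
        cfg = GAConfig(**{**ga_config.__dict__,
                          "chromosome_length": gds.n_sites,
                          "seed": _derive_seed(ga_config.seed, 3, gi)})
        try:
            results[label] = run_ga(
                gds, cfg, gbr_params, parallelism_degree=parallelism_degree,
                target_size=target_size, folds=folds,
            )
        except Exception as exc:  # noqa: BLE001 - reported per group
            failures[label] = exc
    if failures:
        detail = "; ".join(f"group {label}: {exc}" for label, exc in failures.items())
        raise RuntimeError(f"GA failed for {len(failures)} group(s): {detail}")
    return results
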