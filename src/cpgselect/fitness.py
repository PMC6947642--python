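"""Chromosome evaluation: dataset reduction, sample partitioning,
per-partition cross-validated gradient-boosted regression, metric
averaging, and the MAD-plus-sparsity fitness.

A chromosome's fitness is computed by a map/reduce contract: each
(chromosome, partition) pair is an independent work unit producing partial
metrics (map); partials are averaged per chromosome (reduce).  Work-unit
seeds are derived deterministically from (master seed, chromosome key,
partition index), so results are bit-identical at any parallelism degree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

from .data import DataError, MethylationDataset

__all__ = [
    "GBRParams",
    "Metrics",
    "FitnessRecord",
    "PartitionPlan",
    "PENALTY_SITES_PER_UNIT",
    "reduce_dataset",
    "plan_partitions",
    "compute_metrics",
    "cv_regress_partition",
    "evaluate_chromosome",
    "evaluate_population",
]

#: one fitness unit is added to the MAD per this many selected sites
PENALTY_SITES_PER_UNIT = 50


@dataclass
class GBRParams:
    """Gradient-boosted regression-tree hyperparameters.

    Defaults follow the reference configuration: 300 LAD trees of depth 4,
    learning rate 0.03, 60% subsampling.
    """

    n_estimators: int = 300
    max_depth: int = 4
    min_samples_split: int = 2
    subsample: float = 0.6
    alpha: float = 0.6
    learning_rate: float = 0.03
    loss: str = "absolute_error"
    warm_start: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss in ("lad", "least absolute deviation"):
            self.loss = "absolute_error"
        if self.n_estimators < 1:
            raise DataError("n_estimators must be >= 1")
        if self.learning_rate <= 0:
            raise DataError("learning_rate must be positive")
        if not 0 < self.subsample <= 1:
            raise DataError("subsample must lie in (0, 1]")

    def build(self, random_state: int) -> GradientBoostingRegressor:
        kwargs = dict(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            subsample=self.subsample,
            learning_rate=self.learning_rate,
            loss=self.loss,
            warm_start=self.warm_start,
            random_state=random_state,
        )
        if self.loss in ("huber", "quantile"):
            kwargs["alpha"] = self.alpha
        return GradientBoostingRegressor(**kwargs)


@dataclass
class Metrics:
    """Regression quality: MAD and MSE/RMSE in years, plus R^2.

    ``r2`` is None when the true ages have zero variance (undefined).
    """

    mad: float
    mse: float
    rmse: float
    r2: float | None


@dataclass
class FitnessRecord:
    """Partition-averaged metrics plus the sparsity-penalized fitness."""

    metrics: Metrics
    n_selected: int
    fitness: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fitness is None:
            self.fitness = self.metrics.mad + self.n_selected / PENALTY_SITES_PER_UNIT


@dataclass
class PartitionPlan:
    """Disjoint, balanced sample-index partitions covering a dataset."""

    partitions: list[np.ndarray]
    seed: int

    @property
    def n_samples(self) -> int:
        return int(sum(len(p) for p in self.partitions))


def reduce_dataset(ds: MethylationDataset, chromosome: np.ndarray) -> MethylationDataset:
    """Keep only the sites whose gene is 1 (original order, all samples)."""
    chromosome = np.asarray(chromosome)
    if chromosome.shape != (ds.n_sites,):
        raise DataError(
            f"chromosome length {chromosome.shape} does not match {ds.n_sites} sites"
        )
    keep = np.flatnonzero(chromosome == 1)
    if keep.size == 0:
        raise DataError("all-zero chromosome selects no sites")
    if keep.size == ds.n_sites:
        return ds.copy()
    return ds.select_sites(keep)


def plan_partitions(n_samples: int, target_size: int = 100, seed: int = 0) -> PartitionPlan:
    """Shuffle samples and deal them into ``max(1, n // target_size)`` balanced parts."""
    if n_samples < 1:
        raise DataError("need at least one sample")
    if target_size < 1:
        raise DataError("target_size must be positive")
    n_parts = max(1, n_samples // target_size)
    perm = np.random.default_rng(seed).permutation(n_samples)
    partitions = [np.sort(chunk) for chunk in np.array_split(perm, n_parts)]
    return PartitionPlan(partitions=partitions, seed=seed)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """MAD, MSE, RMSE, and R^2 of a prediction vector."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size == 0:
        raise DataError("y_true and y_pred must be equal-length non-empty vectors")
    err = y_true - y_pred
    mad = float(np.mean(np.abs(err)))
    mse = float(np.mean(err ** 2))
    rmse = math.sqrt(mse)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = None if ss_tot == 0 else 1.0 - float(np.sum(err ** 2)) / ss_tot
    return Metrics(mad=mad, mse=mse, rmse=rmse, r2=r2)


def cv_regress_partition(
    X: np.ndarray,
    y: np.ndarray,
    params: GBRParams,
    folds: int = 3,
    seed: int = 0,
) -> Metrics:
    """K-fold CV gradient-boosted regression on one partition.

    Out-of-fold predictions are pooled and scored once.  Partitions smaller
    than ``folds`` fall back to a single fit-and-score with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise DataError("X must be 2-D with at least one feature")
    n = len(y)
    if n < folds:
        warnings.warn(f"partition of {n} samples is smaller than {folds} folds; "
                      "fitting on the full partition")
        model = params.build(random_state=seed)
        model.fit(X, y)
        return compute_metrics(y, model.predict(X))
    pred = np.empty(n)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in kf.split(X):
        model = params.build(random_state=seed)
        model.fit(X[tr], y[tr])
        pred[te] = model.predict(X[te])
    return compute_metrics(y, pred)


def _unit_seed(master: int, chrom_key: int, part_idx: int) -> int:
    return int(np.random.SeedSequence([master, chrom_key, part_idx]).generate_state(1)[0])


def _average_metrics(parts: Sequence[Metrics]) -> Metrics:
    """Arithmetic mean of each metric over partitions (R^2 over defined ones)."""
    r2s = [m.r2 for m in parts if m.r2 is not None]
    return Metrics(
        mad=float(np.mean([m.mad for m in parts])),
        mse=float(np.mean([m.mse for m in parts])),
        rmse=float(np.mean([m.rmse for m in parts])),
        r2=float(np.mean(r2s)) if r2s else None,
    )


_WORST = FitnessRecord(
    metrics=Metrics(mad=math.inf, mse=math.inf, rmse=math.inf, r2=None),
    n_selected=0,
    fitness=math.inf,
)


def _partition_metrics(
    ds: MethylationDataset,
    chromosome: np.ndarray,
    plan: PartitionPlan,
    params: GBRParams,
    folds: int,
    chrom_key: int,
    part_idx: int,
) -> Metrics:
    """One map work unit: CV metrics of one chromosome on one partition."""
    try:
        idx = plan.partitions[part_idx]
        reduced = ds.beta[np.ix_(idx, np.flatnonzero(chromosome == 1))]
        return cv_regress_partition(
            reduced, ds.age[idx], params, folds=folds,
            seed=_unit_seed(params.seed, chrom_key, part_idx),
        )
    except Exception as exc:  # noqa: BLE001 - unit id must reach the caller
        raise RuntimeError(
            f"work unit (chromosome key {chrom_key}, partition {part_idx}) failed: {exc}"
        ) from exc


def evaluate_chromosome(
    ds: MethylationDataset,
    chromosome: np.ndarray,
    plan: PartitionPlan,
    params: GBRParams,
    folds: int = 3,
    chrom_key: int = 0,
) -> FitnessRecord:
    """Fitness of one chromosome: partition-averaged CV MAD + count/50.

    An all-zero chromosome gets the worst-possible (+inf) fitness instead of
    an error so the GA tolerates degenerate offspring.
    """
    chromosome = np.asarray(chromosome)
    if chromosome.shape != (ds.n_sites,):
        raise DataError("chromosome length must equal the site count")
    if plan.n_samples != ds.n_samples:
        raise DataError("partition plan does not cover the dataset")
    n_selected = int((chromosome == 1).sum())
    if n_selected == 0:
        return _WORST
    parts = [
        _partition_metrics(ds, chromosome, plan, params, folds, chrom_key, p)
        for p in range(len(plan.partitions))
    ]
    return FitnessRecord(metrics=_average_metrics(parts), n_selected=n_selected)


def evaluate_population(
    ds: MethylationDataset,
    chromosomes: Sequence[np.ndarray],
    plan: PartitionPlan,
    params: GBRParams,
    parallelism_degree: int = 1,
    folds: int = 3,
    chrom_keys: Sequence[int] | None = None,
) -> list[FitnessRecord]:
    """Map/reduce fitness evaluation of a whole population.

    Each (chromosome, partition) pair is an independent work unit; units may
    run concurrently (``parallelism_degree`` threads) and partial metrics
    are averaged per chromosome.  Results are bit-identical for any degree.
    """
    if parallelism_degree < 1:
        raise DataError("parallelism_degree must be >= 1")
    if chrom_keys is None:
        chrom_keys = list(range(len(chromosomes)))
    if len(chrom_keys) != len(chromosomes):
        raise DataError("one chrom_key required per chromosome")
    units = []
    n_selected = []
    for ci, chrom in enumerate(chromosomes):
        chrom = np.asarray(chrom)
        if chrom.shape != (ds.n_sites,):
            raise DataError(f"chromosome {ci} length must equal the site count")
        n_selected.append(int((chrom == 1).sum()))
        if n_selected[-1] > 0:
            units.extend((ci, p) for p in range(len(plan.partitions)))
    results = Parallel(n_jobs=parallelism_degree, prefer="threads")(
        delayed(_partition_metrics)(ds, chromosomes[ci], plan, params, folds,
                                    chrom_keys[ci], p)
        for ci, p in units
    )
    partials: dict[int, list[Metrics]] = {}
    for (ci, _p), metrics in zip(units, results):
        partials.setdefault(ci, []).append(metrics)
    records: list[FitnessRecord] = []
    for ci in range(len(chromosomes)):
        if n_selected[ci] == 0:
            records.append(_WORST)
        else:
            records.append(FitnessRecord(metrics=_average_metrics(partials[ci]),
                                         n_selected=n_selected[ci]))
    return records
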