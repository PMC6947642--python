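"""Cleaning pipeline: drop all-null rows/columns, mean-impute, min-max
normalize, remove outlier samples, and split train/test."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import DataError, MethylationDataset

__all__ = [
    "SplitResult",
    "drop_all_null",
    "site_means",
    "impute_mean",
    "normalization_stats",
    "normalize",
    "remove_outliers",
    "split_train_test",
    "preprocess_dataset",
]


@dataclass
class SplitResult:
    train: MethylationDataset
    test: MethylationDataset
    seed: int
    ratio: float


def drop_all_null(ds: MethylationDataset) -> MethylationDataset:
    """Remove samples and sites that are completely missing (order preserved)."""
    row_ok = ~np.isnan(ds.beta).all(axis=1)
    col_ok = ~np.isnan(ds.beta).all(axis=0)
    if not row_ok.any() or not col_ok.any():
        raise DataError("dataset is entirely missing")
    out = ds
    if not row_ok.all():
        out = out.select_samples(np.flatnonzero(row_ok))
    if not col_ok.all():
        out = out.select_sites(np.flatnonzero(col_ok))
    return out


def site_means(ds: MethylationDataset) -> np.ndarray:
    """Per-site mean over non-missing cells; errors on all-missing sites."""
    all_missing = np.isnan(ds.beta).all(axis=0)
    if all_missing.any():
        bad = ds.site_ids[int(np.flatnonzero(all_missing)[0])]
        raise DataError(f"site {bad!r} is entirely missing; run drop_all_null first")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(ds.beta, axis=0)


def impute_mean(ds: MethylationDataset, means: np.ndarray | None = None) -> MethylationDataset:
    """Replace missing cells by the per-site mean.

    ``means`` may be supplied (e.g. computed on the train split) to impute
    held-out data without leakage; defaults to the dataset's own site means.
    """
    if means is None:
        means = site_means(ds)
    means = np.asarray(means, dtype=float)
    if means.shape != (ds.n_sites,):
        raise DataError("means length must equal site count")
    out = ds.copy()
    rows, cols = np.nonzero(np.isnan(out.beta))
    out.beta[rows, cols] = means[cols]
    return out


def normalization_stats(ds: MethylationDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (min, max) used by :func:`normalize`."""
    if np.isnan(ds.beta).any():
        raise DataError("normalization requires an imputed dataset")
    return ds.beta.min(axis=0), ds.beta.max(axis=0)


def normalize(
    ds: MethylationDataset,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> MethylationDataset:
    """Per-site min-max scaling to [0, 1]; constant sites map to 0.

    With ``stats`` from another split, scaled values are clipped back into
    [0, 1] so the beta-range invariant survives out-of-range held-out data.
    """
    if np.isnan(ds.beta).any():
        raise DataError("normalize requires an imputed dataset")
    mins, maxs = normalization_stats(ds) if stats is None else stats
    span = maxs - mins
    out = ds.copy()
    scaled = np.zeros_like(out.beta)
    nonconst = span > 0
    scaled[:, nonconst] = (out.beta[:, nonconst] - mins[nonconst]) / span[nonconst]
    out.beta = np.clip(scaled, 0.0, 1.0)
    return out


def remove_outliers(ds: MethylationDataset, z_threshold: float = 3.0) -> MethylationDataset:
    """Drop samples whose mean beta is a z-score outlier (single pass).

    A sample is removed when its mean beta deviates from the cohort
    mean-of-means by more than ``z_threshold`` standard deviations.  With
    fewer than 3 samples this is a no-op.
    """
    if np.isnan(ds.beta).any():
        raise DataError("remove_outliers requires an imputed dataset")
    if ds.n_samples < 3:
        return ds.copy()
    means = ds.beta.mean(axis=1)
    sd = means.std()
    if sd == 0:
        return ds.copy()
    keep = np.abs(means - means.mean()) <= z_threshold * sd
    return ds.select_samples(np.flatnonzero(keep))


def split_train_test(
    ds: MethylationDataset, ratio: float = 2.0 / 3.0, seed: int = 0
) -> SplitResult:
    """Uniform random train/test split without replacement (seeded).

    ``round(ratio * n)`` samples go to train, clamped so neither side is
    empty.
    """
    if not 0 < ratio < 1:
        raise DataError("split ratio must lie in (0, 1)")
    n = ds.n_samples
    if n < 2:
        raise DataError("need at least 2 samples to split")
    n_train = int(np.floor(ratio * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return SplitResult(
        train=ds.select_samples(train_idx),
        test=ds.select_samples(test_idx),
        seed=seed,
        ratio=ratio,
    )


def preprocess_dataset(ds: MethylationDataset, z_threshold: float = 3.0) -> MethylationDataset:
    """drop-all-null -> mean-impute -> min-max normalize -> remove outliers."""
    out = drop_all_null(ds)
    out = impute_mean(out)
    out = normalize(out)
    return remove_outliers(out, z_threshold=z_threshold)
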