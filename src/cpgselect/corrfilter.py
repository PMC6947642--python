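"""Pre-GA dimensionality reduction: rank CpGs by |Pearson r| with age."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import DataError, MethylationDataset

__all__ = ["CorrelationRanking", "rank_by_pearson", "take_top_k", "DEFAULT_TOP_K"]

DEFAULT_TOP_K = 8000


@dataclass
class CorrelationRanking:
    """Sites ordered by decreasing |r| against age (ties by site id)."""

    site_ids: list[str]
    r_values: np.ndarray

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, dtype=float)
        if len(self.site_ids) != len(self.r_values):
            raise DataError("one r value required per site")


def rank_by_pearson(ds: MethylationDataset) -> CorrelationRanking:
    """Pearson correlation of every site with age, ranked by |r|.

    Zero-variance sites (and all sites when age has zero variance) get
    r = 0.  Ties in |r| are broken by ascending site id.
    """
    if ds.age is None:
        raise DataError("ranking requires ages")
    if ds.n_samples < 3:
        raise DataError("ranking requires at least 3 samples")
    if np.isnan(ds.beta).any():
        raise DataError("ranking requires an imputed dataset")
    x = ds.beta - ds.beta.mean(axis=0)
    y = ds.age - ds.age.mean()
    sx = np.sqrt((x ** 2).sum(axis=0))
    sy = np.sqrt((y ** 2).sum())
    r = np.zeros(ds.n_sites)
    ok = (sx > 0) & (sy > 0)
    r[ok] = (x[:, ok] * y[:, None]).sum(axis=0) / (sx[ok] * sy)
    r = np.clip(r, -1.0, 1.0)
    order = sorted(range(ds.n_sites), key=lambda j: (-abs(r[j]), ds.site_ids[j]))
    return CorrelationRanking(
        site_ids=[ds.site_ids[j] for j in order],
        r_values=r[order],
    )


def take_top_k(ranking: CorrelationRanking, k: int = DEFAULT_TOP_K) -> list[str]:
    """First ``min(k, total)`` sites of the ranking; warns when k > total."""
    if k < 1:
        raise DataError("k must be at least 1")
    total = len(ranking.site_ids)
    if k > total:
        warnings.warn(f"requested top {k} sites but only {total} available")
    return list(ranking.site_ids[: min(k, total)])
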