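"""Stepwise forward ranking of a GA-selected CpG panel.

Sites enter one at a time: each round adds the candidate whose inclusion
most decreases the cross-validated MAD (the decrease must exceed a
threshold), then sweeps the previously included sites and eliminates any
whose removal no longer hurts -- a site made redundant by a later arrival
drops out.  The procedure stops when no addition qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

from .data import DataError, MethylationDataset, SelectionReport
from .fitness import GBRParams, compute_metrics

__all__ = ["SFSConfig", "sfs_rank"]


@dataclass
class SFSConfig:
    """Stepwise-selection knobs."""

    #: minimum CV-MAD decrease (years) for an addition to qualify
    improvement_epsilon: float = 0.01
    max_sites: int | None = None
    folds: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.improvement_epsilon < 0:
            raise DataError("improvement_epsilon must be >= 0")
        if self.max_sites is not None and self.max_sites < 1:
            raise DataError("max_sites must be >= 1 when set")
        if self.folds < 2:
            raise DataError("folds must be >= 2")


def sfs_rank(
    ds: MethylationDataset,
    gbr_params: GBRParams,
    sfs_config: SFSConfig | None = None,
    group_label: str = "",
) -> SelectionReport:
    """Rank ``ds``'s sites by stepwise forward selection with elimination.

    ``ds`` should be a group train set restricted to the GA-selected panel.
    The report records the addition order and the CV-MAD after each accepted
    addition (post-elimination); the trajectory decreases by at least
    ``improvement_epsilon`` at every accepted step.  Candidate ties are
    broken by ascending site id.
    """
    config = sfs_config or SFSConfig()
    config.validate()
    if ds.n_sites < 1:
        raise DataError("stepwise selection needs at least one candidate site")
    if ds.age is None:
        raise DataError("stepwise selection requires ages")
    if ds.n_samples < config.folds:
        raise DataError(f"need at least {config.folds} samples for {config.folds}-fold CV")

    y = ds.age
    col = {s: j for j, s in enumerate(ds.site_ids)}
    splits = list(
        KFold(n_splits=config.folds, shuffle=True, random_state=config.seed).split(ds.beta)
    )
    cache: dict[frozenset, float] = {}

    def cv_mad(sites: tuple[str, ...]) -> float:
        key = frozenset(sites)
        if key in cache:
            return cache[key]
        pred = np.empty_like(y)
        if not sites:
            for tr, te in splits:
                pred[te] = y[tr].mean()
        else:
            X = ds.beta[:, [col[s] for s in sites]]
            for tr, te in splits:
                model = gbr_params.build(random_state=config.seed)
                model.fit(X[tr], y[tr])
                pred[te] = model.predict(X[te])
        mad = float(np.mean(np.abs(y - pred)))
        cache[key] = mad
        return mad

    eps = config.improvement_epsilon
    included: list[str] = []
    recorded_mad: dict[str, float] = {}
    current = cv_mad(())

    while config.max_sites is None or len(included) < config.max_sites:
        best_site, best_mad = None, None
        for site in sorted(s for s in ds.site_ids if s not in included):
            mad = cv_mad(tuple(included) + (site,))
            if best_mad is None or mad < best_mad:
                best_site, best_mad = site, mad
        if best_site is None or current - best_mad < eps:
            break
        included.append(best_site)
        current = best_mad
        # backward sweep: drop earlier sites the newcomer made redundant
        for site in list(included[:-1]):
            trimmed = tuple(s for s in included if s != site)
            mad = cv_mad(trimmed)
            if mad <= current + eps:
                included.remove(site)
                recorded_mad.pop(site, None)
                current = mad
        recorded_mad[best_site] = current

    final_sites = tuple(included)
    final: dict[str, float | None] = {"cv_mad": cv_mad(final_sites)}
    if final_sites:
        pred = np.empty_like(y)
        X = ds.beta[:, [col[s] for s in final_sites]]
        for tr, te in splits:
            model = gbr_params.build(random_state=config.seed)
            model.fit(X[tr], y[tr])
            pred[te] = model.predict(X[te])
        m = compute_metrics(y, pred)
        final.update(mad=m.mad, mse=m.mse, rmse=m.rmse, r2=m.r2)
    return SelectionReport(
        group_label=str(group_label),
        ranked_sites=list(included),
        per_site_cv_mad=[recorded_mad[s] for s in included],
        final_metrics=final,
    )
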