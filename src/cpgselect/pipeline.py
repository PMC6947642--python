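"""End-to-end orchestration: preprocess -> age grouping -> per-group
correlation filter -> GA -> stepwise ranking -> final per-group models.

Train samples are grouped by their true age interval; test samples are
routed to groups by the Stage-1 classifier's *predicted* label and never
influence preprocessing statistics, the filter, the GA or the stepwise
ranking (default ``split-first`` mode).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from .config import PipelineConfig, config_hash
from .corrfilter import rank_by_pearson, take_top_k
from .data import DataError, MethylationDataset, merge_datasets, \
    read_geo_series_matrix, read_methylation_matrix, write_selection_report
from .fitness import GBRParams, Metrics, compute_metrics
from .ga import GAConfig, GAHistory, _derive_seed, run_ga
from .grouping import FIVE_GROUP_SCHEME, GroupingScheme, IDENTITY_SCHEME, \
    THREE_GROUP_SCHEME, assign_groups, cv_confusion, decade_labels, \
    fit_group_classifier, merge_by_confusion
from .preprocess import drop_all_null, impute_mean, normalization_stats, \
    normalize, preprocess_dataset, remove_outliers, site_means, split_train_test
from .sfs import sfs_rank
from .synth import generate_cohort

__all__ = ["PipelineError", "run_pipeline", "evaluate_final_model"]

logger = logging.getLogger("cpgselect")

_FIXED_SCHEMES = {
    "three": THREE_GROUP_SCHEME,
    "five": FIVE_GROUP_SCHEME,
    "identity": IDENTITY_SCHEME,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


@_stage("load")
def _load(config: PipelineConfig) -> MethylationDataset:
    if config.synth is not None:
        ds, _truth = generate_cohort(config.synth)
        return ds
    readers = {
        "matrix": lambda p: read_methylation_matrix(p, age_column=config.age_column),
        "geo": lambda p: read_geo_series_matrix(p, age_field=config.geo_age_field),
    }
    datasets = [readers[config.input_format](p) for p in config.input_paths]
    return datasets[0] if len(datasets) == 1 else merge_datasets(datasets)


@_stage("preprocess")
def _preprocess(ds: MethylationDataset, config: PipelineConfig, seed: int):
    if config.preprocess_mode == "preprocess-first":
        clean = preprocess_dataset(ds, z_threshold=config.z_threshold)
        split = split_train_test(clean, ratio=config.split_ratio, seed=seed)
        return split.train, split.test
    # split-first: fit imputation/normalization on train, apply to test
    ds = drop_all_null(ds)
    split = split_train_test(ds, ratio=config.split_ratio, seed=seed)
    train, test = split.train, split.test
    means = site_means(train)
    train = impute_mean(train, means)
    test = impute_mean(test, means)
    stats = normalization_stats(train)
    train = normalize(train, stats)
    test = normalize(test, stats)
    train = remove_outliers(train, z_threshold=config.z_threshold)
    return train, test


@_stage("grouping")
def _grouping(train: MethylationDataset, test: MethylationDataset,
              config: PipelineConfig, seed: int):
    if config.scheme == "auto":
        confusion = cv_confusion(train, IDENTITY_SCHEME, folds=config.folds,
                                 seed=seed, n_components=config.n_components)
        scheme = merge_by_confusion(confusion, config.target_groups)
    else:
        scheme = _FIXED_SCHEMES[config.scheme]
    classifier = fit_group_classifier(train, scheme,
                                      n_components=config.n_components, seed=seed)
    train_groups = scheme.group_of(decade_labels(train.age))
    train = train.with_group(train_groups)
    test = assign_groups(classifier, test)
    return scheme, train, test


@_stage("filter")
def _filter_group(gtrain: MethylationDataset, k: int) -> list[str]:
    return take_top_k(rank_by_pearson(gtrain), k)


@_stage("ga")
def _ga_group(gtrain: MethylationDataset, config: PipelineConfig, seed: int):
    ga_cfg = GAConfig(**{**dataclasses.asdict(config.ga),
                         "chromosome_length": gtrain.n_sites, "seed": seed})
    gbr = GBRParams(**{**dataclasses.asdict(config.gbr), "seed": seed})
    return run_ga(gtrain, ga_cfg, gbr,
                  parallelism_degree=config.parallelism_degree,
                  target_size=config.target_size, folds=config.folds)


@_stage("sfs")
def _sfs_group(gtrain: MethylationDataset, sites: list[str],
               config: PipelineConfig, seed: int, label: int):
    cfg = dataclasses.replace(config.sfs, seed=seed)
    gbr = GBRParams(**{**dataclasses.asdict(config.gbr), "seed": seed})
    return sfs_rank(gtrain.select_sites(sites), gbr, cfg, group_label=str(label))


def _metrics_dict(m: Metrics | None) -> dict[str, float] | None:
    if m is None:
        return None
    return {"mad": m.mad, "mse": m.mse, "rmse": m.rmse, "r2": m.r2}


def evaluate_final_model(
    train: MethylationDataset,
    test: MethylationDataset,
    selected: Mapping[int, list[str]],
    gbr_params: GBRParams,
) -> dict[str, Any]:
    """Fit one regressor per group on its selected panel and score both splits.

    ``train.group`` must hold the true age-interval label, ``test.group``
    the Stage-1 *predicted* label (test samples are scored by the model of
    their predicted group).  Returns per-group and pooled metrics; a group
    with no routed test samples gets ``None`` test metrics and is excluded
    from the pooled test score.
    """
    if train.group is None or test.group is None:
        raise DataError("both splits must carry group labels")
    missing = sorted(set(np.unique(test.group).tolist()) - set(selected))
    if missing:
        raise DataError(f"test samples routed to group(s) {missing} with no trained model")
    per_group: dict[int, dict[str, Any]] = {}
    pooled: dict[str, dict[str, np.ndarray]] = {
        "train": {"y": [], "pred": []}, "test": {"y": [], "pred": []},
    }
    for label in sorted(selected):
        sites = list(selected[label])
        gtrain = train.select_samples(train.group == label).select_sites(sites)
        model = gbr_params.build(random_state=gbr_params.seed)
        model.fit(gtrain.beta, gtrain.age)
        train_pred = model.predict(gtrain.beta)
        pooled["train"]["y"].append(gtrain.age)
        pooled["train"]["pred"].append(train_pred)
        gtest = test.select_samples(test.group == label)
        if gtest.n_samples:
            gtest = gtest.select_sites(sites)
            test_pred = model.predict(gtest.beta)
            pooled["test"]["y"].append(gtest.age)
            pooled["test"]["pred"].append(test_pred)
            test_metrics = compute_metrics(gtest.age, test_pred)
        else:
            test_metrics = None
        per_group[label] = {
            "n_train": gtrain.n_samples,
            "n_test": gtest.n_samples,
            "train": _metrics_dict(compute_metrics(gtrain.age, train_pred)),
            "test": _metrics_dict(test_metrics),
        }
    out: dict[str, Any] = {"per_group": per_group, "pooled": {}}
    for split in ("train", "test"):
        ys, preds = pooled[split]["y"], pooled[split]["pred"]
        out["pooled"][split] = _metrics_dict(
            compute_metrics(np.concatenate(ys), np.concatenate(preds)) if ys else None
        )
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full two-stage pipeline; returns a deterministic summary.

    When ``config.outdir`` is set, artifacts (run manifest, per-group GA
    histories, selection reports, metrics) are written there, each stamped
    with the config hash and master seed.
    """
    config.validate()
    seed = config.seed
    ds = _load(config)
    logger.info("loaded %d samples x %d sites", ds.n_samples, ds.n_sites)
    train, test = _preprocess(ds, config, _derive_seed(seed, 10))
    logger.info("preprocessed: %d train / %d test samples", train.n_samples, test.n_samples)
    scheme, train, test = _grouping(train, test, config, _derive_seed(seed, 11))
    logger.info("scheme: %s", scheme.partition)

    groups: dict[int, dict[str, Any]] = {}
    selected: dict[int, list[str]] = {}
    histories: dict[int, GAHistory] = {}
    reports = {}
    for gi, label in enumerate(range(1, scheme.n_groups + 1)):
        gtrain = train.select_samples(train.group == label)
        if gtrain.n_samples == 0:
            raise PipelineError("ga", DataError(f"group {label} has no train samples"))
        panel = _filter_group(gtrain, config.filter_k)
        best, history = _ga_group(gtrain.select_sites(panel), config,
                                  _derive_seed(seed, 12, gi))
        ga_sites = [panel[j] for j in np.flatnonzero(best == 1)]
        report = _sfs_group(gtrain, ga_sites, config, _derive_seed(seed, 13, gi), label)
        final_sites = report.ranked_sites if report.ranked_sites else ga_sites
        selected[label] = final_sites
        histories[label] = history
        reports[label] = report
        groups[label] = {
            "n_train": gtrain.n_samples,
            "panel_size": len(panel),
            "ga_selected": ga_sites,
            "ranked_sites": report.ranked_sites,
            "final_sites": final_sites,
            "best_fitness": history.best_fitness[-1],
        }
        logger.info("group %d: GA kept %d sites, SFS ranked %d",
                    label, len(ga_sites), len(report.ranked_sites))

    try:
        evaluation = evaluate_final_model(train, test, selected, config.gbr)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("evaluate", exc) from exc

    summary: dict[str, Any] = {
        "config_hash": config_hash(config),
        "seed": seed,
        "version": __version__,
        "scheme": [list(run) for run in scheme.partition],
        "n_train": train.n_samples,
        "n_test": test.n_samples,
        "groups": groups,
        "evaluation": evaluation,
    }
    if config.outdir is not None:
        _write_artifacts(Path(config.outdir), summary, reports, histories)
    return summary


def _write_artifacts(outdir: Path, summary, reports, histories) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest = {"config_hash": summary["config_hash"], "seed": summary["seed"],
                "version": summary["version"]}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    for label, history in histories.items():
        lines = ["generation,best,avg,worst"]
        for g in range(len(history)):
            lines.append(f"{g},{history.best_fitness[g]!r},"
                         f"{history.avg_fitness[g]!r},{history.worst_fitness[g]!r}")
        (outdir / f"ga_history_group{label}.csv").write_text("\n".join(lines) + "\n")
    for label, report in reports.items():
        write_selection_report(report, outdir / f"selection_group{label}.tsv")
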