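"""Domain types and I/O for methylation beta matrices.

A :class:`MethylationDataset` holds a samples x CpG-sites matrix of beta
values (methylation fractions in [0, 1]), a per-sample chronological age
vector, and an optional per-sample age-group label.  Missing cells are
represented by NaN -- never by zero, which is a legal beta value.

Two on-disk formats are supported:

* a plain delimited matrix (comma or tab separated) with a header row of
  site identifiers, one row per sample, and a reserved ``age`` column;
* the GEO series-matrix text dialect (``!``-prefixed metadata lines, the
  data table between ``!series_matrix_table_begin`` and
  ``!series_matrix_table_end``, first column ``ID_REF``).
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethylationDataset",
    "SelectionReport",
    "read_methylation_matrix",
    "write_methylation_matrix",
    "read_geo_series_matrix",
    "merge_datasets",
    "write_selection_report",
    "read_selection_report",
]


class DataError(ValueError):
    """Raised when an input file or dataset violates the data contract."""


@dataclass
class MethylationDataset:
    """Samples x CpG-sites beta matrix with per-sample age.

    Parameters
    ----------
    sample_ids : list of str
        Unique per-sample identifiers (rows of ``beta``).
    site_ids : list of str
        Unique CpG-site identifiers (columns of ``beta``).
    beta : ndarray, shape (n_samples, n_sites)
        Methylation fractions; missing cells are NaN.
    age : ndarray or None
        Chronological age in years, one entry per sample.
    group : ndarray or None
        Optional per-sample age-group label.
    source : list of str or None
        Per-sample provenance (e.g. originating file), kept through merges.
    """

    sample_ids: list[str]
    site_ids: list[str]
    beta: np.ndarray
    age: np.ndarray | None = None
    group: np.ndarray | None = None
    source: list[str] | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 2:
            raise DataError("beta must be a 2-D samples x sites matrix")
        if self.age is not None:
            self.age = np.asarray(self.age, dtype=float)
        if self.group is not None:
            self.group = np.asarray(self.group)
        self.validate()

    # -- container protocol -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_sites(self) -> int:
        return self.beta.shape[1]

    def validate(self) -> None:
        """Check every dataset invariant; raise :class:`DataError` on violation."""
        n, p = self.beta.shape
        if len(self.sample_ids) != n:
            raise DataError(f"{len(self.sample_ids)} sample ids for {n} beta rows")
        if len(self.site_ids) != p:
            raise DataError(f"{len(self.site_ids)} site ids for {p} beta columns")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise DataError(f"duplicate sample id: {dup!r}")
        dup = _first_duplicate(self.site_ids)
        if dup is not None:
            raise DataError(f"duplicate site id: {dup!r}")
        finite = self.beta[~np.isnan(self.beta)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise DataError("non-missing beta values must lie in [0, 1]")
        if self.age is not None:
            if self.age.shape != (n,):
                raise DataError("age vector length must equal sample count")
            if np.isnan(self.age).any() or (self.age < 0).any():
                raise DataError("ages must be non-negative and non-missing")
        if self.group is not None and self.group.shape != (n,):
            raise DataError("group vector length must equal sample count")
        if self.source is not None and len(self.source) != n:
            raise DataError("source list length must equal sample count")

    def copy(self) -> "MethylationDataset":
        return MethylationDataset(
            sample_ids=list(self.sample_ids),
            site_ids=list(self.site_ids),
            beta=self.beta.copy(),
            age=None if self.age is None else self.age.copy(),
            group=None if self.group is None else self.group.copy(),
            source=None if self.source is None else list(self.source),
        )

    def select_samples(self, index: Sequence[int] | np.ndarray) -> "MethylationDataset":
        """Subset (and/or reorder) samples by positional index."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return MethylationDataset(
            sample_ids=[self.sample_ids[i] for i in index],
            site_ids=list(self.site_ids),
            beta=self.beta[index],
            age=None if self.age is None else self.age[index],
            group=None if self.group is None else self.group[index],
            source=None if self.source is None else [self.source[i] for i in index],
        )

    def select_sites(self, sites: Sequence[str] | Sequence[int] | np.ndarray) -> "MethylationDataset":
        """Subset (and/or reorder) sites by id or positional index."""
        sites = list(sites)
        if sites and isinstance(sites[0], str):
            pos = {s: j for j, s in enumerate(self.site_ids)}
            missing = [s for s in sites if s not in pos]
            if missing:
                raise DataError(f"unknown site ids: {missing[:5]}")
            index = np.array([pos[s] for s in sites], dtype=int)
        else:
            index = np.asarray(sites, dtype=int)
        return MethylationDataset(
            sample_ids=list(self.sample_ids),
            site_ids=[self.site_ids[j] for j in index],
            beta=self.beta[:, index],
            age=None if self.age is None else self.age.copy(),
            group=None if self.group is None else self.group.copy(),
            source=None if self.source is None else list(self.source),
        )

    def with_group(self, group: np.ndarray) -> "MethylationDataset":
        return replace(self.copy(), group=np.asarray(group))


@dataclass
class SelectionReport:
    """Ordered CpG panel for one age group with its selection trajectory.

    ``per_site_cv_mad[i]`` is the cross-validated MAD (years) of the model
    after ``ranked_sites[i]`` entered the panel.
    """

    group_label: str
    ranked_sites: list[str]
    per_site_cv_mad: list[float]
    final_metrics: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ranked_sites) != len(self.per_site_cv_mad):
            raise DataError("one cv_mad entry required per ranked site")
        dup = _first_duplicate(self.ranked_sites)
        if dup is not None:
            raise DataError(f"duplicate ranked site: {dup!r}")


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        head = fh.readline()
    return "\t" if "\t" in head else ","


# ---------------------------------------------------------------------------
# Delimited matrix I/O


def read_methylation_matrix(path: str | Path, age_column: str = "age") -> MethylationDataset:
    """Read a delimited beta matrix (header = site ids, one row per sample).

    The first column carries sample identifiers, ``age_column`` the
    chronological age.  Empty cells are flagged missing (NaN), never zero.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    sep = _sniff_delimiter(path)
    with open(path, "r", newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    dup = _first_duplicate(header[1:])
    if dup is not None:
        raise DataError(f"duplicate column in header of {path}: {dup!r}")
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if age_column not in frame.columns:
        raise DataError(f"age column {age_column!r} not found in {path}")
    age_raw = frame[age_column]
    age = pd.to_numeric(age_raw, errors="coerce")
    if age.isna().any():
        bad = age_raw[age.isna()].iloc[0]
        raise DataError(f"non-numeric age value {bad!r} in {path}")
    betas = frame.drop(columns=[age_column]).apply(pd.to_numeric, errors="raise")
    ds = MethylationDataset(
        sample_ids=[str(s) for s in frame.index],
        site_ids=[str(c) for c in betas.columns],
        beta=betas.to_numpy(dtype=float),
        age=age.to_numpy(dtype=float),
        source=[str(path)] * len(frame),
    )
    return ds


def write_methylation_matrix(ds: MethylationDataset, path: str | Path, sep: str = ",") -> None:
    """Write a dataset in the delimited format read by :func:`read_methylation_matrix`."""
    if ds.age is None:
        raise DataError("cannot write a dataset without ages")
    frame = pd.DataFrame(ds.beta, index=ds.sample_ids, columns=ds.site_ids)
    frame.insert(0, "age", ds.age)
    frame.index.name = "sample_id"
    frame.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# GEO series-matrix dialect

_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def _split_geo_fields(line: str) -> list[str]:
    return [tok.strip().strip('"') for tok in line.rstrip("\n").split("\t")]


def read_geo_series_matrix(path: str | Path, age_field: str = "age") -> MethylationDataset:
    """Read a GEO series-matrix text file, transposed to samples x sites.

    Ages are parsed from ``!Sample_characteristics`` entries matching
    ``"<age_field>: <value>"``.  The characteristics key that encodes age
    varies between series, hence the configurable ``age_field``.  If any
    sample lacks a parseable value the age vector is left unset and a
    warning is emitted.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    characteristics: list[list[str]] = []
    accessions: list[str] | None = None
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path, "r") as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.lower().startswith(_TABLE_BEGIN):
                in_table, saw_begin = True, True
                continue
            if stripped.lower().startswith(_TABLE_END):
                in_table, saw_end = False, True
                continue
            if in_table:
                table_lines.append(line)
            elif stripped.startswith("!Sample_characteristics"):
                characteristics.append(_split_geo_fields(line)[1:])
            elif stripped.startswith("!Sample_geo_accession"):
                accessions = _split_geo_fields(line)[1:]
    if not (saw_begin and saw_end):
        raise DataError(f"{path}: missing series-matrix table delimiter "
                        f"({_TABLE_BEGIN!r}/{_TABLE_END!r})")
    if not table_lines:
        raise DataError(f"{path}: empty series-matrix table")
    table = pd.read_csv(io.StringIO("".join(table_lines)), sep="\t", index_col=0)
    table.index = [str(i).strip('"') for i in table.index]
    table.columns = [str(c).strip('"') for c in table.columns]
    sample_ids = accessions if accessions is not None else list(table.columns)
    if len(sample_ids) != table.shape[1]:
        raise DataError(f"{path}: {len(sample_ids)} sample accessions for "
                        f"{table.shape[1]} table columns")

    age = _parse_geo_ages(characteristics, len(sample_ids), age_field, path)
    return MethylationDataset(
        sample_ids=[str(s) for s in sample_ids],
        site_ids=list(table.index),
        beta=table.to_numpy(dtype=float).T,
        age=age,
        source=[str(path)] * len(sample_ids),
    )


def _parse_geo_ages(
    characteristics: list[list[str]], n_samples: int, age_field: str, path: Path
) -> np.ndarray | None:
    pattern = re.compile(rf"^\s*{re.escape(age_field)}\s*[:=]\s*(.+)$", re.IGNORECASE)
    if not characteristics:
        return None
    ages = np.full(n_samples, np.nan)
    for row in characteristics:
        for j, cell in enumerate(row[:n_samples]):
            m = pattern.match(cell)
            if m:
                try:
                    ages[j] = float(m.group(1).split()[0])
                except ValueError:
                    pass
    if np.isnan(ages).any():
        if not np.isnan(ages).all():
            warnings.warn(
                f"{path}: characteristics field {age_field!r} unparseable for "
                f"{int(np.isnan(ages).sum())}/{n_samples} samples; age left unset"
            )
        return None
    return ages


# ---------------------------------------------------------------------------
# Merging


def merge_datasets(datasets: Sequence[MethylationDataset]) -> MethylationDataset:
    """Concatenate cohorts over the intersection of their CpG panels.

    Column order follows the first dataset restricted to the intersection.
    Duplicate sample ids across inputs are disambiguated by suffixing and a
    warning; per-sample provenance is retained.
    """
    if not datasets:
        raise DataError("merge_datasets requires at least one dataset")
    for k, ds in enumerate(datasets):
        if ds.age is None:
            raise DataError(f"dataset {k} has no ages; merging requires ages")
    common = set(datasets[0].site_ids)
    for ds in datasets[1:]:
        common &= set(ds.site_ids)
    if not common:
        raise DataError("datasets share no CpG sites")
    sites = [s for s in datasets[0].site_ids if s in common]

    parts = [ds.select_sites(sites) for ds in datasets]
    sample_ids: list[str] = []
    seen: set[str] = set()
    renamed = 0
    for ds in parts:
        for sid in ds.sample_ids:
            new = sid
            k = 1
            while new in seen:
                new = f"{sid}_{k}"
                k += 1
            if new != sid:
                renamed += 1
            seen.add(new)
            sample_ids.append(new)
    if renamed:
        warnings.warn(f"{renamed} duplicate sample ids disambiguated by suffixing")
    source: list[str] = []
    for k, ds in enumerate(parts):
        source.extend(ds.source if ds.source is not None else [f"dataset_{k}"] * ds.n_samples)
    return MethylationDataset(
        sample_ids=sample_ids,
        site_ids=sites,
        beta=np.vstack([ds.beta for ds in parts]),
        age=np.concatenate([ds.age for ds in parts]),
        source=source,
    )


# ---------------------------------------------------------------------------
# Selection reports


def write_selection_report(report: SelectionReport, path: str | Path) -> None:
    """Write a ranked-panel report as tab-delimited text.

    Layout: ``#``-prefixed metadata lines (group label, final metrics), then
    a header ``rank\tsite_id\tcv_mad_after_addition`` and one row per site.
    """
    path = Path(path)
    try:
        fh = open(path, "w", newline="")
    except OSError as exc:
        raise DataError(f"cannot write selection report to {path}: {exc}") from exc
    with fh:
        fh.write(f"# group: {report.group_label}\n")
        for key in sorted(report.final_metrics):
            val = report.final_metrics[key]
            fh.write(f"# final_{key}: {'' if val is None else repr(float(val))}\n")
        fh.write("rank\tsite_id\tcv_mad_after_addition\n")
        for rank, (site, mad) in enumerate(zip(report.ranked_sites, report.per_site_cv_mad), 1):
            fh.write(f"{rank}\t{site}\t{mad!r}\n")


def read_selection_report(path: str | Path) -> SelectionReport:
    """Read back a report written by :func:`write_selection_report`."""
    path = Path(path)
    group = ""
    metrics: dict[str, float] = {}
    sites: list[str] = []
    mads: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# group:"):
                group = line.split(":", 1)[1].strip()
            elif line.startswith("# final_"):
                key, _, val = line[len("# final_"):].partition(":")
                metrics[key.strip()] = float(val) if val.strip() else None
            elif line and not line.startswith("#") and not line.startswith("rank\t"):
                _, site, mad = line.split("\t")
                sites.append(site)
                mads.append(float(mad))
    return SelectionReport(group_label=group, ranked_sites=sites,
                           per_site_cv_mad=mads, final_metrics=metrics)
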