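"""Age-range grouping: decade labels, PCA + linear-SVM classification,
cross-validated confusion matrices, and confusion-driven class merging.

Ages 0-103 are first binned into ten decade classes.  A linear SVM on
PCA-projected betas predicts the class; classes that the classifier
confuses are merged (only adjacent classes, so groups stay age intervals)
until the desired number of age groups remains.  The fixed 5-group and
3-group schemes used by the reference pipeline are provided alongside the
automated merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .data import DataError, MethylationDataset

__all__ = [
    "MAX_AGE",
    "GroupingScheme",
    "ConfusionMatrix",
    "GroupClassifier",
    "IDENTITY_SCHEME",
    "FIVE_GROUP_SCHEME",
    "THREE_GROUP_SCHEME",
    "decade_labels",
    "apply_scheme",
    "fit_group_classifier",
    "cv_confusion",
    "merge_by_confusion",
    "assign_groups",
]

MAX_AGE = 103.0
_N_CLASSES = 10


@dataclass(frozen=True)
class GroupingScheme:
    """Ordered partition of the ten decade classes into age groups.

    Each partition element is a run of consecutive decade classes, so each
    group corresponds to an age interval; intervals are left-closed and
    right-open except the last, which is closed at ``MAX_AGE``.
    """

    partition: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        flat = [c for run in self.partition for c in run]
        if flat != list(range(1, _N_CLASSES + 1)):
            raise DataError(
                "partition must cover decade classes 1..10 exactly once, in order"
            )
        for run in self.partition:
            if list(run) != list(range(run[0], run[-1] + 1)):
                raise DataError(f"classes {run} are not consecutive")

    @property
    def n_groups(self) -> int:
        return len(self.partition)

    @property
    def boundaries(self) -> list[tuple[float, float]]:
        """Age interval (lo, hi) induced by each group; tiles [0, MAX_AGE]."""
        out = []
        for run in self.partition:
            lo = (run[0] - 1) * 10.0
            hi = MAX_AGE if run[-1] == _N_CLASSES else run[-1] * 10.0
            out.append((lo, hi))
        return out

    @property
    def cutpoints(self) -> list[float]:
        """Interior age boundaries between groups (e.g. [20, 50])."""
        return [b[0] for b in self.boundaries[1:]]

    def group_of(self, decade_label: np.ndarray | int) -> np.ndarray | int:
        """Vectorized :func:`apply_scheme`."""
        lut = np.empty(_N_CLASSES + 1, dtype=int)
        for g, run in enumerate(self.partition, start=1):
            for c in run:
                lut[c] = g
        labels = np.asarray(decade_label)
        out = lut[labels]
        return int(out) if np.isscalar(decade_label) else out


IDENTITY_SCHEME = GroupingScheme(tuple((c,) for c in range(1, 11)))
#: classes (1), (2,3), (4,5), (6,7), (8,9,10)
FIVE_GROUP_SCHEME = GroupingScheme(((1,), (2, 3), (4, 5), (6, 7), (8, 9, 10)))
#: classes (1,2), (3,4,5), (6..10) -> age groups [0,20), [20,50), [50,103]
THREE_GROUP_SCHEME = GroupingScheme(((1, 2), (3, 4, 5), (6, 7, 8, 9, 10)))


def decade_labels(ages: np.ndarray) -> np.ndarray:
    """Decade class 1..10 per age; ages in [90, 103] all fall in class 10."""
    ages = np.asarray(ages, dtype=float)
    if (ages < 0).any() or (ages > MAX_AGE).any():
        raise DataError(f"ages must lie in [0, {MAX_AGE:g}]")
    return np.minimum(np.floor(ages / 10).astype(int) + 1, _N_CLASSES)


def apply_scheme(decade_label: int, scheme: GroupingScheme) -> int:
    """1-based index of the scheme group containing ``decade_label``."""
    if not 1 <= int(decade_label) <= _N_CLASSES:
        raise DataError("decade label must lie in 1..10")
    return int(scheme.group_of(int(decade_label)))


@dataclass
class ConfusionMatrix:
    """Aggregated cross-validated confusion counts.

    ``class_order[i]`` is the run of decade classes behind row/column ``i``.
    """

    counts: np.ndarray
    class_order: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.class_order)
        if self.counts.shape != (n, n):
            raise DataError("confusion counts must be square over class_order")
        if (self.counts < 0).any():
            raise DataError("confusion counts must be non-negative")


@dataclass
class GroupClassifier:
    """Fitted PCA -> linear-SVM group predictor tied to a grouping scheme."""

    model: Pipeline
    scheme: GroupingScheme
    site_ids: list[str]
    n_components: int

    def predict(self, ds: MethylationDataset) -> np.ndarray:
        if list(ds.site_ids) != list(self.site_ids):
            if set(ds.site_ids) == set(self.site_ids):
                ds = ds.select_sites(list(self.site_ids))
            else:
                raise DataError("dataset sites do not match the fitted classifier")
        return self.model.predict(ds.beta)


def _make_model(n_components: int, seed: int) -> Pipeline:
    return Pipeline([
        ("pca", PCA(n_components=n_components, random_state=seed)),
        ("svm", SVC(kernel="linear", C=1.0, random_state=seed)),
    ])


def _group_labels(train: MethylationDataset, scheme: GroupingScheme) -> np.ndarray:
    if train.age is None:
        raise DataError("training data must carry ages")
    return scheme.group_of(decade_labels(train.age))


def fit_group_classifier(
    train: MethylationDataset,
    scheme: GroupingScheme = THREE_GROUP_SCHEME,
    n_components: int = 60,
    seed: int = 0,
) -> GroupClassifier:
    """Fit PCA (``n_components``) + linear SVM on scheme labels of ``train``."""
    y = _group_labels(train, scheme)
    if n_components > min(train.n_samples, train.n_sites):
        raise DataError(
            f"n_components={n_components} exceeds min(samples, sites)="
            f"{min(train.n_samples, train.n_sites)}"
        )
    present = set(np.unique(y).tolist())
    for g in range(1, scheme.n_groups + 1):
        if g not in present:
            raise DataError(f"scheme group {g} has no training samples")
    model = _make_model(n_components, seed)
    model.fit(train.beta, y)
    return GroupClassifier(model=model, scheme=scheme,
                           site_ids=list(train.site_ids), n_components=n_components)


def cv_confusion(
    train: MethylationDataset,
    scheme: GroupingScheme = IDENTITY_SCHEME,
    folds: int = 3,
    seed: int = 0,
    n_components: int = 60,
) -> ConfusionMatrix:
    """K-fold cross-validated confusion matrix over scheme groups.

    Every sample is predicted exactly once by a model not trained on it.
    """
    y = _group_labels(train, scheme)
    labels = list(range(1, scheme.n_groups + 1))
    counts_per_class = np.bincount(y, minlength=scheme.n_groups + 1)[1:]
    for g, c in zip(labels, counts_per_class):
        if 0 < c < folds:
            raise DataError(
                f"group {g} ({scheme.partition[g - 1]}) has {c} samples; "
                f"{folds}-fold CV needs at least {folds}"
            )
    if n_components > min(train.n_samples, train.n_sites):
        raise DataError("n_components exceeds min(samples, sites)")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.zeros_like(y)
    for fold_train, fold_test in skf.split(train.beta, y):
        k = min(n_components, len(fold_train))
        model = _make_model(k, seed)
        model.fit(train.beta[fold_train], y[fold_train])
        pred[fold_test] = model.predict(train.beta[fold_test])
    counts = _sk_confusion(y, pred, labels=labels)
    return ConfusionMatrix(counts=counts, class_order=list(scheme.partition))


def merge_by_confusion(confusion: ConfusionMatrix, target_groups: int) -> GroupingScheme:
    """Greedily merge the most-confused adjacent classes down to ``target_groups``.

    At each step the adjacent pair with the highest symmetrized confusion
    rate -- (counts between the pair, both directions) / (total counts of the
    pair) -- is merged and the matrix re-aggregated.  Ties go to the lower
    class index, making the result deterministic.
    """
    counts = np.asarray(confusion.counts, dtype=float)
    runs = [tuple(r) for r in confusion.class_order]
    if target_groups < 1 or target_groups > len(runs):
        raise DataError(f"target_groups must lie in 1..{len(runs)}")
    while len(runs) > target_groups:
        best_i, best_rate = 0, -1.0
        for i in range(len(runs) - 1):
            between = counts[i, i + 1] + counts[i + 1, i]
            total = counts[i].sum() + counts[i + 1].sum()
            rate = between / total if total > 0 else 0.0
            if rate > best_rate:
                best_i, best_rate = i, rate
        i = best_i
        counts[i] += counts[i + 1]
        counts[:, i] += counts[:, i + 1]
        counts = np.delete(np.delete(counts, i + 1, axis=0), i + 1, axis=1)
        runs[i] = runs[i] + runs[i + 1]
        del runs[i + 1]
    return GroupingScheme(tuple(runs))


def assign_groups(classifier: GroupClassifier, test: MethylationDataset) -> MethylationDataset:
    """Attach the classifier's *predicted* group label to every test sample."""
    pred = classifier.predict(test)
    return test.with_group(pred.astype(int))
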