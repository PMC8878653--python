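"""Recognition-accuracy protocol: splits, confusion matrices, baselines.

The standard per-subject protocol collects a balanced set of gesture
windows (128 per subject: 64 grasp, 64 open), randomly assigns half to
training and half to testing (stratified), and scores each classifier by

    accuracy = (total - errors) / total * 100  =  100 * trace(CM) / total

on the confusion matrix CM of true-by-predicted counts.  Alongside the
Fisher discriminant, three stock baselines are provided for comparison —
Gaussian naive Bayes (NB), k-nearest neighbours (KNN, k = 5) and a CART
decision tree (DT, depth 4) — via scikit-learn.  A pluggable classifier
slot lets callers add further baselines (e.g. an SVM) without touching
the harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .features import LabeledFeatureSet
from .lda import fit_lda, predict

NB_VAR_SMOOTHING = 1e-9   # variance floor, as a fraction of the largest feature variance
KNN_DEFAULT_K = 5
DT_DEFAULT_DEPTH = 4


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split sizes and reproducibility seed."""

    n_train: int = 64
    n_test: int = 64
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must be >= 1")


@dataclass
class ConfusionMatrix:
    """True-by-predicted count table over a fixed class order."""

    counts: np.ndarray
    class_labels: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.class_labels)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be square over class_labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_labels,
                            columns=self.class_labels)


def confusion_matrix(y_true, y_pred, class_labels=None) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if class_labels is None:
        class_labels = sorted(set(y_true) | set(y_pred))
    index = {c: i for i, c in enumerate(class_labels)}
    counts = np.zeros((len(class_labels), len(class_labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(class_labels))


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent correct: 100 * (total - off-diagonal errors) / total."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    errors = total - int(np.trace(cm.counts))
    return 100.0 * (total - errors) / total


def split_dataset(fs: LabeledFeatureSet, spec: SplitSpec):
    """Seeded, reproducible, disjoint train/test split.

    Stratified by default: class counts in each side match the class
    proportions of the full set to within one window.
    """
    m = fs.n_windows
    if spec.n_train + spec.n_test > m:
        raise ValueError(
            f"split {spec.n_train}+{spec.n_test} exceeds {m} available windows"
        )
    rng = np.random.default_rng(spec.seed)
    if not spec.stratified:
        perm = rng.permutation(m)
        tr = perm[:spec.n_train]
        te = perm[spec.n_train:spec.n_train + spec.n_test]
        return fs.select(np.sort(tr)), fs.select(np.sort(te))

    labels = fs.labels.astype(str)
    classes, inverse = np.unique(labels, return_inverse=True)
    tr_idx, te_idx = [], []
    tr_rem, te_rem = spec.n_train, spec.n_test
    for i, cls in enumerate(classes):
        members = rng.permutation(np.nonzero(inverse == i)[0])
        frac = len(members) / m
        n_tr = min(int(round(spec.n_train * frac)), tr_rem, len(members))
        n_te = min(int(round(spec.n_test * frac)), te_rem,
                   len(members) - n_tr)
        tr_idx.extend(members[:n_tr])
        te_idx.extend(members[n_tr:n_tr + n_te])
        tr_rem -= n_tr
        te_rem -= n_te
    if tr_rem or te_rem:
        # Rounding shortfall: top up from unused windows, preserving disjointness.
        used = set(tr_idx) | set(te_idx)
        leftovers = rng.permutation([i for i in range(m) if i not in used])
        tr_idx.extend(leftovers[:tr_rem])
        te_idx.extend(leftovers[tr_rem:tr_rem + te_rem])
    return fs.select(np.sort(tr_idx)), fs.select(np.sort(te_idx))


def subsample_per_class(fs: LabeledFeatureSet, n_per_class: int,
                        seed: int = 0) -> LabeledFeatureSet:
    """Random balanced subsample: ``n_per_class`` windows of each class."""
    rng = np.random.default_rng(seed)
    labels = fs.labels.astype(str)
    keep = []
    for cls in np.unique(labels):
        members = np.nonzero(labels == cls)[0]
        if len(members) < n_per_class:
            raise ValueError(
                f"class {cls!r} has {len(members)} windows, need {n_per_class}"
            )
        keep.extend(rng.choice(members, size=n_per_class, replace=False))
    return fs.select(np.sort(keep))


# ---------------------------------------------------------------------------
# Classifier routes.  Each takes (train, test) LabeledFeatureSets and
# returns a ConfusionMatrix over the union of class labels.

def _class_order(train, test):
    return sorted(set(train.labels.astype(str)) | set(test.labels.astype(str)))


def classify_lda(train: LabeledFeatureSet, test: LabeledFeatureSet,
                 ridge_eps: float | None = None) -> ConfusionMatrix:
    """The from-scratch Fisher discriminant route."""
    model = fit_lda(train, ridge_eps=ridge_eps)
    y = predict(model, test.matrix)
    return confusion_matrix(test.labels, y, _class_order(train, test))


def baseline_nb(train: LabeledFeatureSet, test: LabeledFeatureSet) -> ConfusionMatrix:
    """Gaussian naive Bayes (per-class per-feature normal fit)."""
    clf = GaussianNB(var_smoothing=NB_VAR_SMOOTHING)
    clf.fit(train.matrix, train.labels.astype(str))
    y = clf.predict(test.matrix)
    return confusion_matrix(test.labels, y, _class_order(train, test))


def baseline_knn(train: LabeledFeatureSet, test: LabeledFeatureSet,
                 k: int = KNN_DEFAULT_K) -> ConfusionMatrix:
    """Euclidean k-nearest-neighbour majority vote."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > train.n_windows:
        raise ValueError(f"k={k} exceeds {train.n_windows} training windows")
    clf = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    clf.fit(train.matrix, train.labels.astype(str))
    y = clf.predict(test.matrix)
    return confusion_matrix(test.labels, y, _class_order(train, test))


def baseline_dt(train: LabeledFeatureSet, test: LabeledFeatureSet,
                max_depth: int = DT_DEFAULT_DEPTH) -> ConfusionMatrix:
    """CART decision tree with Gini impurity; deterministic fit."""
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    clf = DecisionTreeClassifier(criterion="gini", max_depth=max_depth,
                                 random_state=0)
    clf.fit(train.matrix, train.labels.astype(str))
    y = clf.predict(test.matrix)
    return confusion_matrix(test.labels, y, _class_order(train, test))


DEFAULT_CLASSIFIERS = {
    "NB": baseline_nb,
    "KNN": baseline_knn,
    "DT": baseline_dt,
    "LDA": classify_lda,
}


@dataclass
class ComparisonReport:
    """Per-subject, per-classifier accuracies plus confusion matrices."""

    accuracies: pd.DataFrame                 # rows: classifiers, cols: subjects + Average
    confusions: dict = field(default_factory=dict)  # (classifier, subject) -> ConfusionMatrix

    def to_csv(self, path) -> None:
        self.accuracies.to_csv(path, float_format="%.2f")


def compare_classifiers(subjects, spec: SplitSpec | None = None,
                        classifiers: dict | None = None) -> ComparisonReport:
    """Run every classifier on every subject with identical splits.

    ``subjects`` is a sequence of per-subject :class:`LabeledFeatureSet`
    objects.  A classifier that raises marks its cell NaN rather than
    aborting the comparison.  Extra classifiers may be supplied as
    ``{"name": callable(train, test) -> ConfusionMatrix}``.
    """
    subjects = list(subjects)
    if not subjects:
        raise ValueError("need at least one subject dataset")
    spec = spec or SplitSpec()
    routes = dict(DEFAULT_CLASSIFIERS)
    if classifiers:
        routes.update(classifiers)
    names = [f"S{i + 1}" for i in range(len(subjects))]
    table = pd.DataFrame(index=list(routes), columns=names, dtype=float)
    confusions = {}
    for sname, fs in zip(names, subjects):
        train, test = split_dataset(fs, spec)
        for cname, route in routes.items():
            try:
                cm = route(train, test)
            except Exception:
                table.loc[cname, sname] = np.nan
                continue
            confusions[(cname, sname)] = cm
            table.loc[cname, sname] = accuracy(cm)
    table["Average"] = table[names].mean(axis=1)
    return ComparisonReport(table, confusions)
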