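"""Between-subject identity decoding with nested cross-validation.

Classifiers are trained on response patterns from all but one subject and
all but one head view, and tested on the left-out subject's patterns at the
left-out view, so above-chance performance requires identity information
that generalizes across both brains and viewpoints.  With 14 subjects and 5
views this yields 5 x 14 = 70 folds; each training set holds
(n_subjects - 1) x n_identities x (n_views - 1) samples and each test set
the left-out subject's n_identities samples at the left-out view.

The classifier is a linear maximum-margin (SVM) multiclass scheme:
one-vs-one with vote counting, ties broken by summed decision values and
then by the lowest class index.  The regularization parameter scales
automatically with the data norm (C = 1 / mean squared sample norm) unless
configured otherwise.  Features receive no additional scaling beyond the
upstream t-values / z-scored patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

CHANCE_4WAY = 0.25


class IncompleteDesignError(ValueError):
    """Raised when a (identity, view) condition is missing from a run set."""


@dataclass(frozen=True)
class FoldSpec:
    """One nested cross-validation fold: a left-out subject and view."""

    test_subject: int
    test_view: int
    train_subjects: tuple
    train_views: tuple

    def __post_init__(self):
        if self.test_subject in self.train_subjects:
            raise ValueError("test subject leaked into training subjects")
        if self.test_view in self.train_views:
            raise ValueError("test view leaked into training views")


@dataclass
class SampleSet:
    """Run-averaged response patterns for one familiarity condition.

    ``data`` is (n_subjects, n_samples, n_nodes) with exactly
    n_identities x n_views samples per subject, labeled by ``identities``
    and ``views``.
    """

    data: np.ndarray
    identities: np.ndarray
    views: np.ndarray
    familiarity: str = "task"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.identities = np.asarray(self.identities)
        self.views = np.asarray(self.views)
        n_id = len(np.unique(self.identities))
        n_view = len(np.unique(self.views))
        if self.data.shape[1] != n_id * n_view:
            raise ValueError(
                f"expected {n_id * n_view} samples per subject, got "
                f"{self.data.shape[1]}"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_views(self) -> int:
        return len(np.unique(self.views))

    @property
    def n_identities(self) -> int:
        return len(np.unique(self.identities))


@dataclass
class ClassifierConfig:
    """Linear SVM settings for fold-level classification."""

    c_mode: str = "norm_scaled"  # or "fixed"
    C: float = 1.0
    normalize_features: bool = False


@dataclass
class AccuracyResult:
    """Per-location, per-fold decoding accuracies."""

    locations: list  # searchlight center nodes or ROI names
    accuracies: np.ndarray  # (n_locations, n_folds)
    folds: list
    familiarity: str = "task"

    def __post_init__(self):
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if np.any(self.accuracies < 0) or np.any(self.accuracies > 1):
            raise ValueError("accuracies must lie in [0, 1]")

    def mean_map(self) -> np.ndarray:
        """Across-fold mean accuracy per location."""
        return self.accuracies.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, loc in enumerate(self.locations):
            for j, fold in enumerate(self.folds):
                rows.append(
                    {
                        "condition": self.familiarity,
                        "location": loc,
                        "fold_subject": fold.test_subject,
                        "fold_view": fold.test_view,
                        "accuracy": self.accuracies[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def average_runs(patterns, familiarity: str = None) -> SampleSet:
    """Average per-run patterns across runs into one sample per condition.

    ``patterns`` is a list with one PatternSet per subject (already
    restricted to a single familiarity, or pass ``familiarity`` to select).
    Every (identity, view) pair must be present in at least one run.
    """
    mats, ids, views = [], None, None
    fam = familiarity or "task"
    for ps in patterns:
        if familiarity is not None:
            ps = ps.select(familiarity)
        meta = ps.meta
        if len(meta) == 0:
            raise IncompleteDesignError("no samples for requested familiarity")
        grouped = (
            pd.DataFrame(ps.data)
            .groupby([meta["identity"], meta["view"]], sort=True)
            .mean()
        )
        idx = grouped.index.to_frame(index=False)
        n_id = meta["identity"].nunique()
        n_view = meta["view"].nunique()
        if len(grouped) != n_id * n_view:
            missing = {
                (i, v)
                for i in meta["identity"].unique()
                for v in meta["view"].unique()
            } - set(map(tuple, idx.to_numpy()))
            raise IncompleteDesignError(f"missing conditions: {sorted(missing)}")
        mats.append(grouped.to_numpy())
        ids = idx["identity"].to_numpy()
        views = idx["view"].to_numpy()
    return SampleSet(np.stack(mats), ids, views, fam)


def make_folds(n_subjects: int, n_views: int) -> list:
    """All (left-out subject, left-out view) pairs, subject-major order."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for between-subject folds")
    if n_views < 2:
        raise ValueError("need at least 2 views for cross-view folds")
    return [
        FoldSpec(
            s,
            v,
            tuple(t for t in range(n_subjects) if t != s),
            tuple(w for w in range(n_views) if w != v),
        )
        for s in range(n_subjects)
        for v in range(n_views)
    ]


def _fit_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    config: ClassifierConfig,
) -> np.ndarray:
    """One-vs-one linear max-margin fit via a precomputed Gram matrix.

    Norm-scaled regularization (C = 1 / mean squared training-sample norm)
    is implemented by normalizing the Gram matrix to unit mean diagonal and
    fitting at C = 1, which yields the identical decision rule.
    """
    K = train_X @ train_X.T
    Kt = test_X @ train_X.T
    if config.c_mode == "norm_scaled":
        scale = K.diagonal().mean()
        C = 1.0
        if scale > 0:
            K = K / scale
            Kt = Kt / scale
    else:
        C = config.C
    clf = SVC(kernel="precomputed", C=C)
    clf.fit(K, train_y)
    return clf.predict(Kt)


def _fold_accuracy(
    loc_data: np.ndarray,
    samples: SampleSet,
    fold: FoldSpec,
    config: ClassifierConfig,
) -> float:
    """Fit and score one fold on pre-sliced (n_subjects, n_samples, k) data."""
    train_mask = np.isin(samples.views, fold.train_views)
    test_mask = samples.views == fold.test_view
    train_X = loc_data[np.ix_(np.asarray(fold.train_subjects),
                              np.flatnonzero(train_mask))].reshape(
        -1, loc_data.shape[2]
    )
    train_y = np.tile(samples.identities[train_mask], len(fold.train_subjects))
    test_X = loc_data[fold.test_subject][test_mask]
    test_y = samples.identities[test_mask]
    if len(np.unique(train_y)) < 2:
        raise ValueError("training labels contain fewer than 2 classes")
    if config.normalize_features:
        mu, sd = train_X.mean(0), train_X.std(0)
        sd[sd == 0] = 1.0
        train_X = (train_X - mu) / sd
        test_X = (test_X - mu) / sd
    pred = _fit_predict(train_X, train_y, test_X, config)
    return float(np.mean(pred == test_y))


def run_fold(
    samples: SampleSet,
    node_idx: np.ndarray,
    fold: FoldSpec,
    config: ClassifierConfig = None,
) -> float:
    """Train on the fold's training subjects/views, test on the left-out
    subject at the left-out view; returns the fraction of correct identity
    predictions."""
    if config is None:
        config = ClassifierConfig()
    node_idx = np.asarray(node_idx)
    if node_idx.size == 0:
        raise ValueError("empty node set")
    return _fold_accuracy(
        np.ascontiguousarray(samples.data[:, :, node_idx]), samples, fold,
        config,
    )


def _accuracies_over(
    samples: SampleSet, node_sets: list, folds: list, config: ClassifierConfig
) -> np.ndarray:
    acc = np.empty((len(node_sets), len(folds)))
    for i, nodes in enumerate(node_sets):
        loc_data = np.ascontiguousarray(samples.data[:, :, np.asarray(nodes)])
        for j, fold in enumerate(folds):
            acc[i, j] = _fold_accuracy(loc_data, samples, fold, config)
    return acc


def searchlight_mvpc(
    samples: SampleSet,
    searchlights: list,
    folds: list,
    config: ClassifierConfig = None,
) -> AccuracyResult:
    """Decoding accuracy per searchlight (accuracy placed at the center node)
    and per cross-validation fold."""
    if config is None:
        config = ClassifierConfig()
    node_sets = [sl.member_nodes for sl in searchlights]
    acc = _accuracies_over(samples, node_sets, folds, config)
    return AccuracyResult(
        [sl.center_node for sl in searchlights], acc, folds, samples.familiarity
    )


def roi_mvpc(
    samples: SampleSet,
    rois,
    folds: list,
    config: ClassifierConfig = None,
) -> AccuracyResult:
    """Decoding accuracy per ROI; ROI node sets replace searchlight disks."""
    if config is None:
        config = ClassifierConfig()
    node_sets, names = [], []
    for name in rois.roi_names:
        nodes = rois.nodes(name)
        if nodes.size == 0:
            raise ValueError(f"ROI {name!r} is empty")
        node_sets.append(nodes)
        names.append(name)
    acc = _accuracies_over(samples, node_sets, folds, config)
    return AccuracyResult(names, acc, folds, samples.familiarity)
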