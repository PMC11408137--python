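"""Wrapper objective: cross-validated accuracy minus a subset-size penalty.

For a binary feature mask X over n genes the objective is

    f(X) = w1 * accuracy(X) - w2 * |X| / n

where accuracy(X) is the mean held-out-fold accuracy of a classifier trained
on the selected gene columns, and |X| is the number of selected genes.  With
w1 >> w2 accuracy dominates and the penalty breaks ties toward smaller
subsets.  Standard confusion-matrix metrics (accuracy, precision, recall,
F-measure) live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sklearn
from sklearn.base import clone
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .datasets import ExpressionDataset, FoldAssignment


@dataclass(frozen=True)
class FitnessWeights:
    """w1 weights accuracy, w2 the selected fraction of genes."""

    w1: float = 0.99
    w2: float = 0.01

    def __post_init__(self):
        if self.w1 <= 0:
            raise ValueError("w1 must be positive")
        if self.w2 < 0:
            raise ValueError("w2 must be non-negative")


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the four derived metrics."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f_measure: float


def evaluate_confusion(y_true, y_pred, positive_class) -> MetricsReport:
    """Exact confusion-matrix metrics for one positive class.

    Accuracy = (TP+TN)/total, precision = TP/(TP+FP), recall = TP/(TP+FN),
    F-measure = harmonic mean of precision and recall.  Zero-denominator
    cases (no predicted positives, no true positives) yield 0 by convention.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("empty label vectors")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    tp = int(np.sum(pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    acc = (tp + tn) / len(y_true)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    fm = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return MetricsReport(tp, tn, fp, fn, acc, prec, rec, fm)


class ClassifierAdapter:
    """Deterministic fit/predict wrapper around an sklearn estimator.

    The estimator is cloned once at construction so the caller's instance is
    never mutated; :meth:`fit` then refits that private copy (sklearn's fit
    resets all learned state, so refitting with identical inputs and seed
    yields identical predictions).
    """

    def __init__(self, estimator):
        self.estimator = clone(estimator)
        self._fitted = None

    def fit(self, X, y) -> "ClassifierAdapter":
        self._fitted = self.estimator.fit(X, y)
        return self

    def predict(self, X):
        if self._fitted is None:
            raise RuntimeError("fit must be called before predict")
        return self._fitted.predict(X)


def make_classifier(name: str = "svm", seed: int = 0, **kwargs) -> ClassifierAdapter:
    """Build a classifier adapter by short name (default: linear-kernel SVM)."""
    name = name.lower()
    if name == "svm":
        est = SVC(kernel=kwargs.pop("kernel", "linear"), C=kwargs.pop("C", 1.0),
                  random_state=seed, **kwargs)
    elif name == "rf":
        est = RandomForestClassifier(
            n_estimators=kwargs.pop("n_estimators", 100), random_state=seed, **kwargs
        )
    elif name == "dt":
        est = DecisionTreeClassifier(random_state=seed, **kwargs)
    elif name == "nb":
        est = GaussianNB(**kwargs)
    elif name == "knn":
        est = KNeighborsClassifier(n_neighbors=kwargs.pop("n_neighbors", 5), **kwargs)
    else:
        raise ValueError(f"unknown classifier {name!r}; use svm/rf/dt/nb/knn")
    return ClassifierAdapter(est)


def _check_mask(mask, n_genes: int) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape != (n_genes,):
        raise ValueError(f"mask length {mask.shape} does not match {n_genes} genes")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask entries must be 0 or 1")
    if mask.sum() == 0:
        raise ValueError("empty mask: at least one gene must be selected")
    return mask.astype(bool)


def cv_accuracy(
    ds: ExpressionDataset,
    mask,
    classifier: ClassifierAdapter,
    folds: FoldAssignment,
) -> float:
    """Mean held-out-fold accuracy of the classifier on the masked genes."""
    sel = _check_mask(mask, ds.n_genes)
    X = ds.matrix[:, sel]
    y = ds.labels
    accs = []
    # inputs are validated once up front, so skip sklearn's per-fit checks
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        for train_idx, test_idx in folds:
            classifier.fit(X[train_idx], y[train_idx])
            pred = classifier.predict(X[test_idx])
            accs.append(float(np.mean(pred == y[test_idx])))
    return float(np.mean(accs))


def fitness(
    ds: ExpressionDataset,
    mask,
    classifier: ClassifierAdapter,
    folds: FoldAssignment,
    weights: FitnessWeights = FitnessWeights(),
) -> float:
    """One-shot objective f(X) = w1*accuracy - w2*|X|/n (no memoization)."""
    mask = np.asarray(mask)
    acc = cv_accuracy(ds, mask, classifier, folds)
    return weights.w1 * acc - weights.w2 * mask.sum() / ds.n_genes


class FitnessEvaluator:
    """Memoized objective over one (dataset, classifier, fold-set).

    The swarm revisits masks frequently; results are cached by the exact bit
    pattern, so repeated evaluations of one mask cost a single CV.  Call the
    instance with a mask to get f(X); :meth:`accuracy` exposes the cached CV
    accuracy of the same mask.

    ``folds`` may be a single FoldAssignment or a sequence of them; with
    several, the accuracy is averaged over the fold partitions (repeated
    CV).  A wrapper search actively hunts for masks that look perfect on one
    particular partition; averaging over re-drawn partitions damps that
    selection bias.
    """

    def __init__(
        self,
        ds: ExpressionDataset,
        classifier: ClassifierAdapter,
        folds,
        weights: FitnessWeights = FitnessWeights(),
    ):
        self.ds = ds
        self.classifier = classifier
        self.folds = [folds] if isinstance(folds, FoldAssignment) else list(folds)
        if not self.folds:
            raise ValueError("at least one fold assignment is required")
        self.weights = weights
        self.n_genes = ds.n_genes
        self._acc_cache: dict = {}
        self.n_evaluations = 0  # distinct CV computations

    def accuracy(self, mask) -> float:
        mask = np.ascontiguousarray(np.asarray(mask, dtype=np.uint8))
        key = mask.tobytes()
        if key not in self._acc_cache:
            self._acc_cache[key] = float(
                np.mean(
                    [cv_accuracy(self.ds, mask, self.classifier, f) for f in self.folds]
                )
            )
            self.n_evaluations += 1
        return self._acc_cache[key]

    def __call__(self, mask) -> float:
        mask = np.asarray(mask)
        acc = self.accuracy(mask)
        return self.weights.w1 * acc - self.weights.w2 * mask.sum() / self.n_genes
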