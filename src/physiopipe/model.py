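"""Classifier training, leave-one-subject-out evaluation, and t-SNE
feature-space projection.

Four classifier families are supported: a polynomial-kernel SVM
(degree 2), a decision tree, a 100-tree random forest, and k-nearest
neighbours with k = 5 and uniform Euclidean weighting. Evaluation holds
out every subject once (LOSO); "expert" is the positive class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

from .types import EvaluationReport, FeatureMatrix, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpertiseClassifier",
    "loso_folds",
    "fit_predict",
    "compute_metrics",
    "run_experiment",
    "tsne_embed",
    "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = ("svm", "dt", "rf", "knn")
POSITIVE_LABEL = "expert"


class ExpertiseClassifier(ClassifierMixin, BaseEstimator):
    """Standardize-then-classify wrapper around the four supported models.

    Parameters
    ----------
    kind : {"svm", "dt", "rf", "knn"}
        svm — SVC with a second-degree polynomial kernel and
        regularization ``C``; dt — Gini decision tree, unbounded depth;
        rf — random forest of ``n_trees``; knn — k-nearest neighbours
        with ``k`` uniform-weighted Euclidean neighbours.
    random_state : int
        Seed for the stochastic learners (dt, rf).

    The scaler is fit on the training rows only, so cross-validated
    evaluation never leaks held-out statistics.
    """

    def __init__(self, kind: str = "knn", C: float = 1.0, n_trees: int = 100,
                 k: int = 5, random_state: int = 0):
        self.kind = kind
        self.C = C
        self.n_trees = n_trees
        self.k = k
        self.random_state = random_state

    def _make_estimator(self):
        if self.kind == "svm":
            # inhomogeneous quadratic kernel (x·y + 1)^2; coef0=0 would be
            # sign-blind and cannot separate symmetric clusters
            clf = SVC(kernel="poly", degree=2, coef0=1.0, C=self.C)
        elif self.kind == "dt":
            clf = DecisionTreeClassifier(criterion="gini", random_state=self.random_state)
        elif self.kind == "rf":
            clf = RandomForestClassifier(
                n_estimators=self.n_trees, random_state=self.random_state
            )
        elif self.kind == "knn":
            clf = KNeighborsClassifier(
                n_neighbors=self.k, weights="uniform", metric="euclidean"
            )
        else:
            raise InvalidParameterError(
                f"unknown classifier kind {self.kind!r}; choose from {CLASSIFIER_KINDS}"
            )
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])

    def fit(self, X, y):
        X = validate_data(self, X)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise InvalidParameterError("training fold contains a single class")
        self.pipeline_ = self._make_estimator().fit(X, y)
        self.classes_ = self.pipeline_.named_steps["clf"].classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        X = validate_data(self, X, reset=False)
        return self.pipeline_.predict(X)

    def spec(self) -> dict:
        hp = {"kind": self.kind, "random_state": self.random_state}
        if self.kind == "svm":
            hp.update(kernel="poly", degree=2, C=self.C)
        elif self.kind == "dt":
            hp.update(criterion="gini")
        elif self.kind == "rf":
            hp.update(n_trees=self.n_trees)
        elif self.kind == "knn":
            hp.update(k=self.k, weights="uniform", metric="euclidean")
        return hp


def loso_folds(matrix: FeatureMatrix) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-subject-out row-index folds, one per subject.

    Each fold's test set is all windows of exactly one subject; the
    folds partition the matrix.
    """
    groups = matrix.groups
    subjects = pd.unique(groups)
    if subjects.size < 2:
        raise InvalidParameterError("LOSO needs at least 2 subjects")
    folds = []
    for s in subjects:
        test = np.nonzero(groups == s)[0]
        if test.size == 0:
            warnings.warn(f"subject {s} has no rows; excluded from LOSO", UserWarning)
            continue
        train = np.nonzero(groups != s)[0]
        folds.append((train, test))
    return folds


def fit_predict(clf: ExpertiseClassifier, X_train, y_train, X_test) -> np.ndarray:
    """Train on the fold's training rows and label its test rows."""
    fitted = ExpertiseClassifier(**clf.get_params()).fit(X_train, y_train)
    return fitted.predict(X_test)


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from confusion counts.

    Accuracy = (TP+TN)/(TP+FP+TN+FN); Precision = TP/(TP+FP);
    Recall = TP/(TP+FN); F1 = 2·P·R/(P+R). Undefined divisions return
    0 with ``zero_division`` flagged True.
    """
    if min(tp, tn, fp, fn) < 0:
        raise InvalidParameterError("confusion counts must be nonnegative")
    total = tp + tn + fp + fn
    if total == 0:
        raise InvalidParameterError("confusion counts sum to zero")
    flag = False
    accuracy = (tp + tn) / total
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, flag = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, flag = 0.0, True
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1, flag = 0.0, True
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "zero_division": flag,
    }


def _confusion(y_true, y_pred, positive: str = POSITIVE_LABEL) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    return tp, tn, fp, fn


def run_experiment(
    matrix: FeatureMatrix,
    clf: ExpertiseClassifier | None = None,
    aggregation: str = "mean-over-folds",
    seed: int | None = None,
) -> EvaluationReport:
    """LOSO evaluation of one classifier on one feature matrix.

    Per-fold confusion counts are computed with "expert" as the
    positive class and aggregated either by averaging fold metrics
    (default) or by pooling window-level counts across folds.
    """
    if aggregation not in ("mean-over-folds", "pooled-windows"):
        raise InvalidParameterError(f"unknown aggregation {aggregation!r}")
    clf = clf or ExpertiseClassifier(kind="knn")
    if seed is not None:
        clf = ExpertiseClassifier(**{**clf.get_params(), "random_state": seed})
    X, y, groups = matrix.X, matrix.y, matrix.groups
    rows = []
    for train, test in loso_folds(matrix):
        if np.unique(y[train]).size < 2:
            warnings.warn(
                f"fold holding out {groups[test[0]]} has single-class training data; skipped",
                UserWarning,
            )
            continue
        y_pred = fit_predict(clf, X[train], y[train], X[test])
        tp, tn, fp, fn = _confusion(y[test], y_pred)
        rows.append(
            {"held_out_subject": groups[test[0]], "TP": tp, "TN": tn, "FP": fp,
             "FN": fn, **compute_metrics(tp, tn, fp, fn),
             # LOSO folds hold out one subject, so each test set is
             # single-class and precision/recall are undefined on the
             # negative-class folds; definedness masks drive aggregation
             "precision_defined": tp + fp > 0,
             "recall_defined": tp + fn > 0,
             "f1_defined": tp + fp > 0 and tp + fn > 0}
        )
    folds = pd.DataFrame(rows)
    if folds.empty:
        raise InvalidParameterError("no evaluable LOSO folds")
    if aggregation == "mean-over-folds":
        aggregate = {"accuracy": float(folds["accuracy"].mean())}
        for k in ("precision", "recall", "f1"):
            mask = folds[f"{k}_defined"] if f"{k}_defined" in folds else folds["f1_defined"]
            aggregate[k] = float(folds.loc[mask, k].mean()) if mask.any() else 0.0
    else:
        pooled = compute_metrics(
            int(folds["TP"].sum()), int(folds["TN"].sum()),
            int(folds["FP"].sum()), int(folds["FN"].sum()),
        )
        aggregate = {k: pooled[k] for k in ("accuracy", "precision", "recall", "f1")}
    return EvaluationReport(
        folds=folds,
        aggregate=aggregate,
        aggregation=aggregation,
        classifier=clf.spec(),
        seed=seed,
    )


def tsne_embed(
    matrix: FeatureMatrix,
    perplexity: float = 30.0,
    iterations: int = 10_000,
    learning_rate: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """2-D t-SNE projection of the feature space plus a class silhouette.

    Perplexity is reduced (with a warning) when the matrix has fewer
    than 3·perplexity rows. The silhouette score of the true labels on
    the embedding summarizes class separability as a scalar.
    """
    X = StandardScaler().fit_transform(matrix.X)
    n = X.shape[0]
    if n < 3 * perplexity:
        new_p = max((n - 1) / 3.0, 2.0)
        warnings.warn(
            f"perplexity {perplexity} too large for {n} rows; reduced to {new_p:.1f}",
            UserWarning,
        )
        perplexity = new_p
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=iterations,
        learning_rate=learning_rate,
        init="pca" if X.shape[1] >= 2 else "random",
        random_state=seed,
    ).fit_transform(X)
    df = pd.DataFrame(
        {
            "dim1": emb[:, 0],
            "dim2": emb[:, 1],
            "subject_id": matrix.groups,
            "label": matrix.y,
        }
    )
    sil = float(silhouette_score(emb, matrix.y)) if np.unique(matrix.y).size > 1 else np.nan
    return df, sil
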