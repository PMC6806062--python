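"""LASSO-based feature ranking and thresholded selection.

Features are standardized internally (zero mean, unit variance) and an
L1-penalized linear regression of the binary class label on the features
is fit; coefficient magnitudes on the standardized scale rank feature
importance, and features with |coefficient| above a cutoff (default
0.01) are selected. The penalty strength is chosen by 5-fold
cross-validation unless fixed explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import Lasso, LassoCV, LogisticRegression, LogisticRegressionCV
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, validate_data

from .types import FeatureMatrix, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = ["LassoFeatureRanker", "LassoRanking", "lasso_rank", "apply_threshold"]

DEFAULT_THRESHOLD = 0.01


def _hash_folds(X: np.ndarray, n_folds: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic CV splits keyed on row content.

    Rows are assigned to folds by hashing their bytes, so identical rows
    always share a fold and the cross-validated fit is invariant to row
    duplication and row order.
    """
    import hashlib

    ids = np.array(
        [int.from_bytes(hashlib.md5(row.tobytes()).digest()[:4], "little") % n_folds
         for row in np.ascontiguousarray(X)]
    )
    occupied = [f for f in range(n_folds) if np.any(ids == f)]
    if len(occupied) < 2:  # degenerate tiny input: plain contiguous folds
        from sklearn.model_selection import KFold

        return list(KFold(min(n_folds, X.shape[0])).split(X))
    return [
        (np.nonzero(ids != f)[0], np.nonzero(ids == f)[0]) for f in occupied
    ]


@dataclass
class LassoRanking:
    """Signed coefficients (standardized scale) and the selected subset."""

    coefficients: dict[str, float]
    penalty_strength: float
    threshold: float = DEFAULT_THRESHOLD
    selected: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature": list(self.coefficients),
                "coefficient": list(self.coefficients.values()),
            }
        )
        df["abs_coefficient"] = df["coefficient"].abs()
        df["selected"] = df["feature"].isin(self.selected)
        return df.sort_values("abs_coefficient", ascending=False, ignore_index=True)


class LassoFeatureRanker(SelectorMixin, BaseEstimator):
    """Select features whose standardized LASSO coefficient exceeds a cutoff.

    Parameters
    ----------
    alpha : float or "cv"
        L1 penalty strength; "cv" picks it by 5-fold cross-validated
        prediction error.
    threshold : float
        Selection cutoff on |coefficient| (strict inequality).
    family : {"linear", "logistic"}
        Penalized linear regression of the 0/1 label (default, the
        regression framing) or L1 logistic regression.
    random_state : int
        Controls the cross-validation fold shuffling.

    Attributes
    ----------
    coef_ : ndarray
        Signed coefficients on the standardized feature scale.
    alpha_ : float
        Penalty strength actually used.
    """

    def __init__(self, alpha="cv", threshold: float = DEFAULT_THRESHOLD,
                 family: str = "linear", random_state: int = 0):
        self.alpha = alpha
        self.threshold = threshold
        self.family = family
        self.random_state = random_state

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_samples=4)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise InvalidParameterError(
                f"binary labels required, got classes {classes.tolist()}"
            )
        y01 = (y == classes[1]).astype(float)
        if min((y01 == 0).sum(), (y01 == 1).sum()) < 2:
            raise InvalidParameterError("need at least 2 rows per class")

        keep = X.std(axis=0) > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} constant feature column(s)",
                UserWarning,
            )
        Xs = StandardScaler().fit_transform(X[:, keep])

        coefs = np.zeros(X.shape[1])
        if self.family == "linear":
            if self.alpha == "cv":
                cv = LassoCV(cv=_hash_folds(X, 5), max_iter=50_000)
                cv.fit(Xs, y01)
                # one-standard-error rule: largest penalty whose CV error
                # is within one SE of the minimum (stabler, sparser than
                # the raw CV minimum)
                mean_mse = cv.mse_path_.mean(axis=1)
                se = cv.mse_path_.std(axis=1) / np.sqrt(cv.mse_path_.shape[1])
                i_min = int(np.argmin(mean_mse))
                ok = mean_mse <= mean_mse[i_min] + se[i_min]
                alpha = float(cv.alphas_[ok].max())
                model = Lasso(alpha=alpha, max_iter=50_000)
            else:
                model = Lasso(alpha=float(self.alpha), max_iter=50_000)
            model.fit(Xs, y01)
            self.alpha_ = float(model.alpha)
            coefs[keep] = model.coef_
        elif self.family == "logistic":
            if self.alpha == "cv":
                model = LogisticRegressionCV(
                    cv=5, penalty="l1", solver="liblinear",
                    random_state=self.random_state, max_iter=10_000,
                )
            else:
                model = LogisticRegression(
                    penalty="l1", solver="liblinear", C=1.0 / float(self.alpha),
                    max_iter=10_000,
                )
            model.fit(Xs, y01)
            self.alpha_ = (
                1.0 / float(model.C_[0]) if hasattr(model, "C_") else float(self.alpha)
            )
            coefs[keep] = model.coef_.ravel()
        else:
            raise InvalidParameterError(f"unknown family {self.family!r}")

        self.coef_ = coefs
        self.classes_ = classes
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "coef_")
        return np.abs(self.coef_) > self.threshold

    def ranking(self, feature_names=None) -> LassoRanking:
        check_is_fitted(self, "coef_")
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{i}" for i in range(self.coef_.size)]
        )
        coefficients = dict(zip(names, self.coef_.tolist()))
        return LassoRanking(
            coefficients=coefficients,
            penalty_strength=self.alpha_,
            threshold=self.threshold,
            selected=apply_threshold_dict(coefficients, self.threshold),
        )


def lasso_rank(
    matrix: FeatureMatrix,
    penalty="cv",
    threshold: float = DEFAULT_THRESHOLD,
    family: str = "linear",
    random_state: int = 0,
) -> LassoRanking:
    """Rank a feature matrix's columns by standardized LASSO coefficient."""
    ranker = LassoFeatureRanker(
        alpha=penalty, threshold=threshold, family=family, random_state=random_state
    )
    ranker.fit(matrix.X, matrix.y)
    return ranker.ranking(matrix.feature_names)


def apply_threshold_dict(coefficients: dict[str, float], threshold: float) -> list[str]:
    chosen = [(abs(c), name) for name, c in coefficients.items() if abs(c) > threshold]
    return [name for _, name in sorted(chosen, key=lambda t: (-t[0], t[1]))]


def apply_threshold(
    ranking: LassoRanking, threshold: float = DEFAULT_THRESHOLD
) -> list[str]:
    """Features with |coefficient| strictly above the cutoff, ordered by
    descending magnitude (ties broken by name). Empty selections are
    reported with a warning; callers fall back to all features."""
    selected = apply_threshold_dict(ranking.coefficients, threshold)
    if not selected:
        warnings.warn(
            "no feature exceeds the LASSO coefficient cutoff; "
            "falling back to the full feature set",
            UserWarning,
        )
    return selected


def select_features(matrix: FeatureMatrix, ranking: LassoRanking,
                    threshold: float = DEFAULT_THRESHOLD) -> FeatureMatrix:
    """Restrict a matrix to the selected features (all features if the
    selection is empty)."""
    selected = apply_threshold(ranking, threshold)
    if not selected:
        return matrix
    cols = ["subject_id", "label", "window_id", *selected]
    return FeatureMatrix(
        data=matrix.data[cols].copy(),
        modality=matrix.modality,
        normalized=matrix.normalized,
    )


def plot_ranking(ranking: LassoRanking, path, title: str = "LASSO feature importance"):
    """Bar chart of |coefficient| per feature (selected bars highlighted)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = ranking.to_frame()
    fig, ax = plt.subplots(figsize=(8, 0.3 * len(df) + 1.5))
    colors = ["tab:blue" if s else "lightgray" for s in df["selected"]]
    ax.barh(df["feature"][::-1], df["abs_coefficient"][::-1],
            color=colors[::-1])
    ax.axvline(ranking.threshold, color="k", lw=0.8, ls="--")
    ax.set_xlabel("|coefficient| (standardized)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
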