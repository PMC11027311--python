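"""High- vs low-gist classification with a class-rebalanced bagged forest.

Each category dataset is severely imbalanced (e.g. 545 high vs 71 low for
current cancers), so before fitting, the minority class of the *training*
data is oversampled with replacement until the classes are equal; held-out
data is never touched. The classifier is an ensemble of 500
bootstrap-aggregated decision trees. Evaluation uses stratified 10-fold
cross-validation: every image is scored exactly once out-of-fold, the pooled
out-of-fold scores give the AUC, a stratified bootstrap over the scored
images gives its 95% CI, and the 130 per-feature importance scores are
averaged across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

POSITIVE_LABEL = "high"


@dataclass(frozen=True)
class ModelConfig:
    """Classifier and evaluation settings."""

    n_trees: int = 500
    k_folds: int = 10
    oversample: bool = True
    importance_method: str = "impurity"  # or "permutation"
    bootstrap_reps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.importance_method not in ("impurity", "permutation"):
            raise ValueError("importance_method must be 'impurity' or 'permutation'")


@dataclass
class ModelReport:
    """Cross-validated evaluation of one category model."""

    category: str
    out_of_fold_scores: pd.Series
    labels: pd.Series
    auc: float
    auc_ci: tuple[float, float]
    per_fold_auc: list[float]
    importance: pd.Series
    config_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "per_fold_auc": self.per_fold_auc,
            "n_samples": int(len(self.labels)),
            "class_counts": self.labels.value_counts().to_dict(),
            "importance": self.importance.to_dict(),
            "out_of_fold_scores": self.out_of_fold_scores.to_dict(),
            "config": self.config_echo,
        }


def oversample_minority(
    X: pd.DataFrame, y: pd.Series, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Balance classes by resampling minority rows with replacement.

    The originals are kept and enough duplicates are drawn to equalize the
    class counts (71 vs 545 becomes 545 vs 545). Apply to training folds
    only — duplicating before the fold split would leak copies of a sample
    into its own test fold.
    """
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present to oversample")
    minority = counts.idxmin()
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return X, y
    pool = np.flatnonzero((y == minority).to_numpy())
    extra = rng.choice(pool, size=deficit, replace=True)
    take = np.concatenate([np.arange(len(y)), extra])
    return X.iloc[take], y.iloc[take]


class OversampledBaggedForest(ClassifierMixin, BaseEstimator):
    """Bagged decision-tree ensemble with in-fit minority oversampling.

    A scikit-learn classifier: ``fit`` optionally balances the training
    classes by resampling the minority with replacement, then fits a
    500-tree bootstrap-aggregated forest. ``feature_importances_`` holds
    the mean-decrease-in-impurity scores (or permutation importances on the
    original, unbalanced training data when
    ``importance_method='permutation'``).

    Parameters
    ----------
    n_trees : int, default 500
    oversample : bool, default True
    importance_method : {'impurity', 'permutation'}, default 'impurity'
    random_state : int or None
    """

    def __init__(
        self,
        n_trees: int = 500,
        oversample: bool = True,
        importance_method: str = "impurity",
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.oversample = oversample
        self.importance_method = importance_method
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y), index=X.index)
        if y.nunique() < 2:
            raise ValueError("training data contains a single class")
        rng = np.random.default_rng(self.random_state)
        X_fit, y_fit = (
            oversample_minority(X, y, rng) if self.oversample else (X, y)
        )
        forest_seed = int(rng.integers(2**31 - 1))
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=forest_seed
        )
        self.forest_.fit(X_fit.to_numpy(), y_fit.to_numpy())
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        if self.importance_method == "permutation":
            perm = permutation_importance(
                self.forest_,
                X.to_numpy(),
                y.to_numpy(),
                n_repeats=5,
                random_state=forest_seed,
            )
            self.feature_importances_ = np.clip(perm.importances_mean, 0.0, None)
        else:
            self.feature_importances_ = self.forest_.feature_importances_
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(np.asarray(pd.DataFrame(X)))

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(pd.DataFrame(X)))

    def score_high(self, X) -> np.ndarray:
        """Predicted probability of the high-gist class."""
        col = int(np.flatnonzero(self.classes_ == POSITIVE_LABEL)[0])
        return self.predict_proba(X)[:, col]


def compute_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Rank-based (Mann-Whitney) AUC of high-class scores; ties count 1/2."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to compute an AUC")
    return float(roc_auc_score(labels == POSITIVE_LABEL, np.asarray(scores, float)))


def auc_ci(
    scores: Sequence[float],
    labels: Sequence[str],
    reps: int = 2000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """95% stratified-bootstrap percentile interval for the AUC.

    Out-of-fold scored images are resampled with replacement within each
    class; degenerate replicates cannot occur because each class keeps its
    size.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = rng or np.random.default_rng()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == POSITIVE_LABEL)
    neg = np.flatnonzero(labels != POSITIVE_LABEL)
    stats = np.empty(reps)
    for r in range(reps):
        ip = rng.choice(pos, size=pos.size, replace=True)
        ineg = rng.choice(neg, size=neg.size, replace=True)
        take = np.concatenate([ip, ineg])
        stats[r] = compute_auc(scores[take], labels[take])
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def cross_validate(
    X: pd.DataFrame,
    y: pd.Series,
    config: ModelConfig | None = None,
    category: str = "",
) -> ModelReport:
    """Stratified k-fold evaluation of the rebalanced bagged forest.

    Oversampling happens inside each training fold; every image is scored
    exactly once on the fold that held it out. Importances are the mean of
    the per-fold importances. Fully deterministic given ``config.seed``.
    """
    config = config or ModelConfig()
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y), index=X.index)
    class_counts = y.value_counts()
    if len(class_counts) < 2:
        raise ValueError(f"dataset {category!r} contains a single class")
    if class_counts.min() < config.k_folds:
        raise ValueError(
            f"dataset {category!r}: minority class has {class_counts.min()} samples, "
            f"fewer than k_folds={config.k_folds}"
        )
    rng = np.random.default_rng(config.seed)
    skf = StratifiedKFold(
        n_splits=config.k_folds, shuffle=True, random_state=config.seed
    )
    oof = pd.Series(np.nan, index=X.index, dtype=float)
    per_fold_auc: list[float] = []
    importances = []
    for train_idx, test_idx in skf.split(X, y):
        clf = OversampledBaggedForest(
            n_trees=config.n_trees,
            oversample=config.oversample,
            importance_method=config.importance_method,
            random_state=int(rng.integers(2**31 - 1)),
        )
        clf.fit(X.iloc[train_idx], y.iloc[train_idx])
        fold_scores = clf.score_high(X.iloc[test_idx])
        oof.iloc[test_idx] = fold_scores
        per_fold_auc.append(compute_auc(fold_scores, y.iloc[test_idx]))
        importances.append(clf.feature_importances_)
    auc = compute_auc(oof.to_numpy(), y.to_numpy())
    ci = auc_ci(
        oof.to_numpy(), y.to_numpy(), reps=config.bootstrap_reps, rng=rng
    )
    importance = pd.Series(
        np.mean(importances, axis=0), index=X.columns, name="importance"
    )
    return ModelReport(
        category=category,
        out_of_fold_scores=oof,
        labels=y,
        auc=auc,
        auc_ci=ci,
        per_fold_auc=per_fold_auc,
        importance=importance,
        config_echo=asdict(config),
    )
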