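"""Patient-grouped machine-learning validation of the topological features.

The node-level feature table (28 topological features per node, EZ/NEZ
label, patient identifier) is class-balanced 1:1 by seeded undersampling
and evaluated with a nested, patient-grouped protocol: a Group 5-fold
outer loop (no patient ever spans train and test) wraps an inner grouped
3-fold grid search maximizing AUC.  Z-scoring — plain or after a
``log(1 + x)`` transform — is embedded in the pipeline so scaling
statistics always come from training folds only; tree-based models (RF,
GBM) are trained on the original feature space.  Significance of the
pooled AUC is assessed by label-permutation testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import GridSearchCV, GroupKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .metrics import FEATURE_COLUMNS

__all__ = [
    "CVProtocol",
    "ClassifierReport",
    "PermutationResult",
    "LogZTransformer",
    "EZClassifier",
    "balance_classes",
    "log_z_transform",
    "nested_group_cv",
    "evaluate_scores",
    "permutation_test",
    "MODEL_NAMES",
    "SCALED_MODELS",
]

MODEL_NAMES = ("svm", "rf", "gbm", "knn", "lr")
#: Models whose pipelines embed a scaler; trees use the raw feature space.
SCALED_MODELS = ("svm", "knn", "lr")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"model__C": [0.1, 1, 10]},
    "rf": {"model__n_estimators": [50, 100, 200], "model__max_depth": [None, 10, 20]},
    "gbm": {"model__n_estimators": [50, 100, 200], "model__learning_rate": [0.05, 0.1]},
    "knn": {"model__n_neighbors": [3, 5, 7, 9, 11]},
    "lr": {"model__C": [0.1, 1, 10]},
}


@dataclass(frozen=True)
class CVProtocol:
    """Nested patient-grouped cross-validation settings."""

    outer_folds: int = 5
    inner_folds: int = 3
    scoring: str = "roc_auc"
    grids: dict = field(default_factory=lambda: DEFAULT_GRIDS)


class LogZTransformer(BaseEstimator, TransformerMixin):
    """``x -> log(1 + x)`` then Z-score with training-fold statistics.

    ``log1p`` (rather than a bare log) accommodates the exact zeros that
    degree and betweenness take on isolated nodes.  Training columns
    with zero variance transform to 0 after centering.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("features must be nonnegative")
        lx = np.log1p(X)
        self.mean_ = lx.mean(axis=0)
        self.scale_ = lx.std(axis=0, ddof=0)
        self.zero_variance_ = self.scale_ == 0
        self.scale_ = np.where(self.zero_variance_, 1.0, self.scale_)
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("features must be nonnegative")
        return (np.log1p(X) - self.mean_) / self.scale_


def log_z_transform(train: np.ndarray, apply_to: np.ndarray | None = None) -> np.ndarray:
    """Functional form: fit log+Z on ``train``, apply to ``apply_to``."""
    t = LogZTransformer().fit(train)
    return t.transform(train if apply_to is None else apply_to)


def _base_model(name: str, seed: int):
    if name == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if name == "rf":
        return RandomForestClassifier(random_state=seed)
    if name == "gbm":
        return GradientBoostingClassifier(random_state=seed)
    if name == "knn":
        return KNeighborsClassifier()
    if name == "lr":
        return LogisticRegression(max_iter=5000, random_state=seed)
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


class EZClassifier(BaseEstimator, ClassifierMixin):
    """One model of the protocol with its embedded scaler and grid search.

    ``fit(X, y, groups=...)`` runs the inner grouped grid search and
    refits the winning configuration on all training rows.  Scaling
    (``preprocessing='z'`` or ``'log_z'``) is part of the pipeline for
    SVM/KNN/LR and skipped for the tree ensembles.
    """

    def __init__(self, model: str = "svm", preprocessing: str = "log_z",
                 inner_folds: int = 3, scoring: str = "roc_auc",
                 grids: Optional[dict] = None, random_state: int = 0):
        self.model = model
        self.preprocessing = preprocessing
        self.inner_folds = inner_folds
        self.scoring = scoring
        self.grids = grids
        self.random_state = random_state

    def _pipeline(self) -> Pipeline:
        if self.preprocessing not in ("none", "z", "log_z"):
            raise ValueError("preprocessing must be 'none', 'z' or 'log_z'")
        steps = []
        if self.model in SCALED_MODELS and self.preprocessing != "none":
            scaler = StandardScaler() if self.preprocessing == "z" else LogZTransformer()
            steps.append(("scaler", scaler))
        steps.append(("model", _base_model(self.model, self.random_state)))
        return Pipeline(steps)

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("EZClassifier is a binary classifier")
        grid = (self.grids or DEFAULT_GRIDS)[self.model]
        if groups is not None and np.unique(groups).size >= self.inner_folds:
            cv = GroupKFold(n_splits=self.inner_folds)
        else:
            cv = self.inner_folds
        search = GridSearchCV(self._pipeline(), grid, scoring=self.scoring,
                              cv=cv, refit=True)
        search.fit(X, y, groups=groups)
        self.search_ = search
        self.best_params_ = search.best_params_
        self.best_estimator_ = search.best_estimator_
        return self

    def predict(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict_proba(X)

    def decision_scores(self, X) -> np.ndarray:
        """Score in [0, 1] for the positive (EZ) class.

        Probabilistic models report the class probability; margin models
        (SVM) report the sigmoid-squashed decision function, so the 0.5
        threshold coincides with the decision boundary.
        """
        check_is_fitted(self, "best_estimator_")
        est = self.best_estimator_
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, 1]
        from scipy.special import expit

        return expit(est.decision_function(X))


def balance_classes(table: pd.DataFrame, seed: int = 0,
                    label_col: str = "ez_label", group_col: str = "patient_id"
                    ) -> pd.DataFrame:
    """Undersample the majority class to a strict 1:1 ratio (seeded).

    Majority rows are removed proportionally to each patient's share of
    the majority class (largest-remainder allocation), preserving the
    group structure for the grouped folds.
    """
    y = table[label_col].astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if n_pos == n_neg:
        return table.copy()
    majority = y if n_pos > n_neg else ~y
    target = min(n_pos, n_neg)
    maj = table[majority]
    rng = np.random.default_rng(seed)
    shares = maj.groupby(group_col).size()
    quota = shares * target / shares.sum()
    keep_n = np.floor(quota).astype(int)
    remainder = quota - keep_n
    short = target - int(keep_n.sum())
    for g in remainder.sort_values(ascending=False).index[:short]:
        keep_n[g] += 1
    kept = [table[~majority]]
    for g, sub in maj.groupby(group_col):
        if keep_n[g] == 0:
            continue
        idx = rng.choice(sub.index.to_numpy(), size=int(keep_n[g]), replace=False)
        kept.append(sub.loc[np.sort(idx)])
    return pd.concat(kept).sort_index()


@dataclass
class ClassifierReport:
    model: str
    preprocessing: str
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    confusion: np.ndarray  # rows: true (neg, pos)
    fold_params: list
    fold_aucs: list
    fold_test_patients: list
    pooled: bool = True
    oof_scores: np.ndarray | None = None  # pooled out-of-fold scores
    oof_labels: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "model": self.model, "preprocessing": self.preprocessing,
            "auc": self.auc, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "f1": self.f1,
            "confusion": np.asarray(self.confusion).tolist(),
            "fold_params": self.fold_params, "fold_aucs": self.fold_aucs,
        }


@dataclass
class PermutationResult:
    observed_auc: float
    null_aucs: list[float]
    p: float


def evaluate_scores(labels: np.ndarray, scores: np.ndarray,
                    threshold: float = 0.5) -> dict:
    """Confusion-matrix metrics and rank AUC from probability scores."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        auc = float("nan")
    else:
        auc = float(roc_auc_score(labels, scores))
    pred = (scores >= threshold).astype(int)
    cm = confusion_matrix(labels, pred, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    acc = (tp + tn) / cm.sum()
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    return {"auc": auc, "accuracy": float(acc), "sensitivity": float(sens),
            "specificity": float(spec), "precision": float(prec),
            "f1": float(f1), "confusion": cm}


def _table_arrays(table: pd.DataFrame, feature_cols: Sequence[str]):
    X = table[list(feature_cols)].to_numpy(dtype=float)
    y = table["ez_label"].astype(bool).to_numpy().astype(int)
    groups = table["patient_id"].to_numpy()
    return X, y, groups


def nested_group_cv(
    table: pd.DataFrame,
    model: str,
    protocol: CVProtocol | None = None,
    preprocessing: str = "log_z",
    seed: int = 0,
    feature_cols: Sequence[str] = FEATURE_COLUMNS,
    pooled: bool = True,
) -> ClassifierReport:
    """Nested patient-grouped cross-validation of one model.

    Outer Group K-fold by patient; per fold an inner grouped grid search
    selects hyperparameters by AUC, the winner is refit on the full
    outer-training split and scored on the held-out patients.  Metrics
    are computed on the pooled out-of-fold scores (or averaged per fold
    with ``pooled=False``).
    """
    protocol = protocol or CVProtocol()
    X, y, groups = _table_arrays(table, feature_cols)
    n_patients = np.unique(groups).size
    if n_patients < protocol.outer_folds:
        raise ValueError(
            f"{n_patients} patients cannot fill {protocol.outer_folds} outer folds")
    outer = GroupKFold(n_splits=protocol.outer_folds)
    clf = EZClassifier(model=model, preprocessing=preprocessing,
                       inner_folds=protocol.inner_folds, scoring=protocol.scoring,
                       grids=protocol.grids, random_state=seed)
    oof_scores = np.full(len(y), np.nan)
    fold_params, fold_aucs, fold_patients = [], [], []
    for train_idx, test_idx in outer.split(X, y, groups):
        if np.unique(y[train_idx]).size < 2:
            raise ValueError("single-class outer training fold")
        fold_clf = clone(clf)
        fold_clf.fit(X[train_idx], y[train_idx], groups=groups[train_idx])
        s = fold_clf.decision_scores(X[test_idx])
        oof_scores[test_idx] = s
        fold_params.append(fold_clf.best_params_)
        fold_patients.append(sorted(set(groups[test_idx])))
        if np.unique(y[test_idx]).size == 2:
            fold_aucs.append(float(roc_auc_score(y[test_idx], s)))
        else:
            fold_aucs.append(float("nan"))
    if pooled:
        m = evaluate_scores(y, oof_scores)
    else:
        per_fold = [evaluate_scores(y[np.isin(groups, pats)],
                                    oof_scores[np.isin(groups, pats)])
                    for pats in fold_patients]
        m = {k: float(np.nanmean([f[k] for f in per_fold]))
             for k in ("auc", "accuracy", "sensitivity", "specificity",
                       "precision", "f1")}
        m["confusion"] = evaluate_scores(y, oof_scores)["confusion"]
    return ClassifierReport(
        model=model, preprocessing=preprocessing, auc=m["auc"],
        accuracy=m["accuracy"], sensitivity=m["sensitivity"],
        specificity=m["specificity"], precision=m["precision"], f1=m["f1"],
        confusion=m["confusion"], fold_params=fold_params, fold_aucs=fold_aucs,
        fold_test_patients=fold_patients, pooled=pooled,
        oof_scores=oof_scores, oof_labels=y,
    )


def permutation_test(
    table: pd.DataFrame,
    model: str,
    protocol: CVProtocol | None = None,
    preprocessing: str = "log_z",
    n_perm: int = 1000,
    seed: int = 0,
    feature_cols: Sequence[str] = FEATURE_COLUMNS,
) -> PermutationResult:
    """Label-permutation null for the pooled nested-CV AUC.

    Labels are shuffled across the whole table before each full nested
    run; ``p = (1 + #{null >= observed}) / (1 + n_perm)`` never reaches
    exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    observed = nested_group_cv(table, model, protocol, preprocessing,
                               seed=seed, feature_cols=feature_cols).auc
    rng = np.random.default_rng(seed)
    null_aucs = []
    shuffled = table.copy()
    for _ in range(n_perm):
        shuffled = shuffled.assign(
            ez_label=rng.permutation(table["ez_label"].to_numpy()))
        auc = nested_group_cv(shuffled, model, protocol, preprocessing,
                              seed=seed, feature_cols=feature_cols).auc
        null_aucs.append(auc)
    p = (1 + sum(a >= observed for a in null_aucs)) / (1 + n_perm)
    return PermutationResult(observed, null_aucs, float(p))
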