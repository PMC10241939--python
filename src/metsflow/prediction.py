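"""Classifier benchmarking over feature sets with stratified 10-fold CV.

Four classifiers are wired in: XGBoost, random forest, a stacking ensemble
(out-of-fold probabilities from XGBoost and RF fed to a logistic
meta-learner, with a majority-vote variant) and plain logistic regression.
AUC is computed from out-of-fold predicted probabilities per fold; the
confusion-matrix metrics (accuracy, precision, sensitivity, specificity,
F1) use a 0.5 probability threshold by default.

Hyperparameters are fixed defaults, documented in :data:`DEFAULT_PARAMS`;
there is no tuning loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier, StackingClassifier, VotingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .errors import ConfigurationError, MetsflowError

__all__ = [
    "CLASSIFIERS",
    "DEFAULT_PARAMS",
    "ConfusionMatrix",
    "CVReport",
    "ImportanceRanking",
    "compute_metrics",
    "make_classifier",
    "run_cv",
    "feature_importances",
    "importance_share",
    "incremental_auc_curve",
    "shap_values",
]

CLASSIFIERS = ("xgboost", "random_forest", "stacking", "stacking_vote",
               "logistic_regression")

#: Fixed default hyperparameters (no search).
DEFAULT_PARAMS: dict[str, dict] = {
    "xgboost": dict(
        n_estimators=150, max_depth=4, learning_rate=0.1, subsample=0.8,
        colsample_bytree=0.8, tree_method="hist", eval_metric="logloss",
        n_jobs=1,
    ),
    "random_forest": dict(n_estimators=200, min_samples_leaf=2, n_jobs=1),
    "logistic_regression": dict(max_iter=2000),
}


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts at a fixed decision threshold."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ConfigurationError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, precision, sensitivity, specificity and F1 from counts.

    Metrics with a zero denominator are reported as NaN (missing) rather
    than coerced to zero.
    """
    if cm.n == 0:
        raise MetsflowError("empty confusion matrix")
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn)
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return {
        "accuracy": _ratio(cm.tp + cm.tn, cm.n),
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
        "f1": f1,
    }


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the benchmarked classifiers with fixed defaults."""
    if name == "xgboost":
        return XGBClassifier(random_state=seed, **DEFAULT_PARAMS["xgboost"])
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, **DEFAULT_PARAMS["random_forest"])
    if name == "logistic_regression":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(**DEFAULT_PARAMS["logistic_regression"]),
        )
    if name == "stacking":
        return StackingClassifier(
            estimators=[
                ("xgboost", make_classifier("xgboost", seed)),
                ("random_forest", make_classifier("random_forest", seed)),
            ],
            final_estimator=LogisticRegression(max_iter=1000),
            stack_method="predict_proba",
            cv=3,
            n_jobs=1,
        )
    if name == "stacking_vote":
        return VotingClassifier(
            estimators=[
                ("xgboost", make_classifier("xgboost", seed)),
                ("random_forest", make_classifier("random_forest", seed)),
            ],
            voting="hard",
            n_jobs=1,
        )
    raise ConfigurationError(
        f"unknown classifier {name!r}; choose from {CLASSIFIERS}"
    )


@dataclass
class CVReport:
    """Per-fold and summary metrics of one cross-validated run."""

    classifier: str
    feature_set: str
    k: int
    seed: int
    threshold: float
    fold_metrics: pd.DataFrame          # one row per fold
    fold_assignments: np.ndarray        # fold index per sample

    @property
    def mean(self) -> pd.Series:
        return self.fold_metrics.mean()

    @property
    def sd(self) -> pd.Series:
        return self.fold_metrics.std(ddof=1)

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            m: {"mean": float(self.mean[m]), "sd": float(self.sd[m])}
            for m in self.fold_metrics.columns
        }

    def to_json_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "feature_set": self.feature_set,
            "k": self.k,
            "seed": self.seed,
            "threshold": self.threshold,
            "summary": self.summary(),
            "folds": self.fold_metrics.round(6).to_dict(orient="records"),
        }


def _validate_matrix(X: np.ndarray, y: np.ndarray, k: int) -> None:
    if not np.isfinite(X).all():
        raise MetsflowError("non-finite feature values; clean before fitting")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos < k or n_neg < k:
        raise MetsflowError(
            f"need at least k={k} samples per class for stratified folds "
            f"(have {n_pos} positive, {n_neg} negative)"
        )


def run_cv(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int],
    classifier: str = "xgboost",
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
    feature_set: str = "",
) -> CVReport:
    """Stratified k-fold cross-validation of one classifier.

    Folds are stratified (about 8.5% positives makes unstratified folds
    unstable) and shuffled with ``seed``; the whole run is deterministic
    given the seed. AUC per fold comes from out-of-fold predicted
    probabilities; the remaining metrics from a threshold on them (hard
    votes for the majority-vote ensemble, which has no probabilities).
    """
    X_arr = np.asarray(X, dtype=float)
    y_arr = np.asarray(y, dtype=int)
    _validate_matrix(X_arr, y_arr, k)
    model = make_classifier(classifier, seed)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(y_arr), dtype=int)
    rows = []
    for fold, (train, test) in enumerate(splitter.split(X_arr, y_arr)):
        assignments[test] = fold
        fitted = clone(model).fit(X_arr[train], y_arr[train])
        if hasattr(fitted, "predict_proba"):
            proba = fitted.predict_proba(X_arr[test])[:, 1]
            auc = roc_auc_score(y_arr[test], proba)
            pred = (proba >= threshold).astype(int)
        else:
            pred = fitted.predict(X_arr[test]).astype(int)
            auc = roc_auc_score(y_arr[test], pred)
        metrics = compute_metrics(ConfusionMatrix.from_predictions(y_arr[test], pred))
        rows.append({"auc": auc, **metrics})
    return CVReport(
        classifier=classifier,
        feature_set=feature_set,
        k=k,
        seed=seed,
        threshold=threshold,
        fold_metrics=pd.DataFrame(rows),
        fold_assignments=assignments,
    )


@dataclass
class ImportanceRanking:
    """Features ordered by importance score, ties broken lexicographically."""

    pairs: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        self.pairs = sorted(self.pairs, key=lambda p: (-p[1], p[0]))
        total = sum(score for _, score in self.pairs)
        if total > 0:
            self.pairs = [(name, score / total) for name, score in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def features(self) -> list[str]:
        return [name for name, _ in self.pairs]

    def top(self, n: int) -> list[tuple[str, float]]:
        return self.pairs[:n]


def feature_importances(
    X: pd.DataFrame, y, classifier: str = "xgboost", seed: int = 0
) -> ImportanceRanking:
    """Fit on the full data and rank features by the model's importances."""
    model = make_classifier(classifier, seed)
    model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
    if hasattr(model, "feature_importances_"):
        scores = model.feature_importances_
    elif hasattr(model, "named_steps"):
        scores = np.abs(model.named_steps["logisticregression"].coef_.ravel())
    else:
        raise ConfigurationError(f"classifier {classifier!r} exposes no importances")
    return ImportanceRanking(list(zip(list(X.columns), map(float, scores))))


def importance_share(
    ranking: ImportanceRanking, top_n: int, group: str,
    groups: Mapping[str, Sequence[str]],
) -> float:
    """Share of the top-``top_n`` importance mass carried by one provenance group."""
    if top_n > len(ranking):
        raise ConfigurationError(f"top_n={top_n} exceeds ranking length {len(ranking)}")
    if group not in groups:
        raise ConfigurationError(f"unknown feature group {group!r}")
    members = set(groups[group])
    top = ranking.top(top_n)
    total = sum(score for _, score in top)
    if total == 0:
        return math.nan
    return sum(score for name, score in top if name in members) / total


def incremental_auc_curve(
    X: pd.DataFrame,
    y,
    ranking: ImportanceRanking,
    classifier: str = "xgboost",
    k: int = 10,
    seed: int = 0,
    tol: float = 0.002,
    patience: int = 3,
) -> tuple[list[tuple[int, float]], int]:
    """Mean CV AUC as features are added one by one in importance order.

    Returns the curve ``[(n_features, mean_auc), ...]`` and the convergence
    point: the smallest n after which ``patience`` consecutive additions
    each gain less than ``tol`` AUC (the full length when never reached).
    """
    if len(ranking) == 0:
        raise ConfigurationError("empty importance ranking")
    features = [f for f in ranking.features if f in X.columns]
    if not features:
        raise ConfigurationError("ranking covers no columns of X")
    curve = []
    for n in range(1, len(features) + 1):
        report = run_cv(X[features[:n]], y, classifier=classifier, k=k, seed=seed)
        curve.append((n, float(report.mean["auc"])))
    convergence = len(features)
    aucs = [auc for _, auc in curve]
    for n in range(1, len(aucs)):
        gains = [aucs[j] - aucs[j - 1] for j in range(n, min(n + patience, len(aucs)))]
        if gains and all(g < tol for g in gains):
            convergence = n
            break
    return curve, convergence


def shap_values(model, X):
    """Optional SHAP hook: tree-explainer values for a fitted tree model.

    Requires the ``shap`` package, which is not a dependency of this
    package; install it separately to use this hook.
    """
    try:
        import shap
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "the SHAP export hook needs the optional 'shap' package"
        ) from exc
    return shap.TreeExplainer(model).shap_values(np.asarray(X, dtype=float))
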