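"""Random-forest classification with stratified k-fold cross-validation.

Two evaluation protocols are provided. ``within-fold`` (default) applies
SMOTE to each training split only, so synthetic points never leak into the
test fold — the methodologically sound protocol. ``paper-mode`` oversamples
the whole dataset first and then folds it, mirroring the workbench workflow
of oversample-then-cross-validate; it is optimistic because synthetic points
derived from test-fold originals can appear in training folds, and it is
kept for comparability with that workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .balance import SmoteConfig, rebalance_dataset
from .metrics import ConfusionMatrix, metrics_report, roc_auc

ARTIFACT_FORMAT_VERSION = 1

CV_MODES = ("within-fold", "paper-mode")


@dataclass(frozen=True)
class RFParams:
    """Random-forest hyperparameters (defaults match common workbench settings)."""

    n_trees: int = 100
    max_features: str | int | float = "sqrt"  # floor(sqrt(d)) per split
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class CVResult:
    """Cross-validation output: pooled confusion matrix plus per-fold detail.

    ``oof_scores`` holds each instance's out-of-fold positive-class vote
    fraction (every original instance is scored exactly once).
    """

    confusion: ConfusionMatrix
    fold_metrics: list[dict] = field(default_factory=list)
    oof_scores: np.ndarray | None = None
    oof_predictions: np.ndarray | None = None
    y: np.ndarray | None = None
    auc: float | None = None
    mode: str = "within-fold"
    folds: int = 10

    def report(self) -> dict:
        out = metrics_report(self.confusion)
        out["auc"] = self.auc
        out["mode"] = self.mode
        out["folds"] = self.folds
        out["fold_metrics"] = self.fold_metrics
        return out


def train_rf(X, y, params: RFParams = RFParams()) -> RandomForestClassifier:
    """Fit a random forest: bootstrap-resampled trees with random feature
    subsets per split; prediction is the majority vote, score the vote
    fraction. Deterministic for a fixed seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=params.max_features,
        max_depth=params.max_depth,
        bootstrap=True,
        random_state=params.seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def positive_score(clf: RandomForestClassifier, X, positive=1) -> np.ndarray:
    """Vote fraction for the positive class."""
    X = np.asarray(X, dtype=float)
    col = list(clf.classes_).index(positive)
    return clf.predict_proba(X)[:, col]


def crossvalidate(
    X,
    y,
    folds: int = 10,
    smote: SmoteConfig | None = None,
    mode: str = "within-fold",
    params: RFParams = RFParams(),
    positive=1,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation with optional SMOTE rebalancing.

    Returns the pooled confusion matrix over out-of-fold predictions,
    per-fold Sn/Sp/Acc/MCC and per-instance out-of-fold scores. In
    ``paper-mode`` the confusion matrix covers original plus synthetic
    instances (the oversampled dataset is what gets folded); out-of-fold
    scores are reported for the original instances only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if mode not in CV_MODES:
        raise ValueError(f"unknown CV mode {mode!r}")
    n_original = len(y)

    if mode == "paper-mode" and smote is not None and smote.percent > 0:
        X_cv, y_cv = rebalance_dataset(X, y, smote, minority_label=positive)
        smote_in_fold = None
    else:
        X_cv, y_cv = X, y
        smote_in_fold = smote

    counts = np.unique(y_cv, return_counts=True)[1]
    if counts.min() < folds:
        # stratification impossible (e.g. leave-one-out); fall back to plain
        # shuffled folds, which still partition every instance exactly once
        if smote_in_fold is not None and smote_in_fold.percent > 0:
            raise ValueError(
                f"smallest class has {counts.min()} members; cannot stratify "
                f"into {folds} folds with within-fold SMOTE"
            )
        if folds > len(y_cv):
            raise ValueError(f"folds={folds} exceeds instance count {len(y_cv)}")
        skf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof_scores = np.full(len(y_cv), np.nan)
    oof_pred = np.empty(len(y_cv), dtype=y_cv.dtype)
    pooled: ConfusionMatrix | None = None
    fold_metrics: list[dict] = []

    for fold_i, (train_idx, test_idx) in enumerate(skf.split(X_cv, y_cv)):
        X_tr, y_tr = X_cv[train_idx], y_cv[train_idx]
        if smote_in_fold is not None and smote_in_fold.percent > 0:
            X_tr, y_tr = rebalance_dataset(X_tr, y_tr, smote_in_fold, minority_label=positive)
        clf = train_rf(X_tr, y_tr, RFParams(
            n_trees=params.n_trees, max_features=params.max_features,
            max_depth=params.max_depth, seed=params.seed + fold_i,
        ))
        pred = clf.predict(X_cv[test_idx])
        oof_pred[test_idx] = pred
        oof_scores[test_idx] = positive_score(clf, X_cv[test_idx], positive)
        cm = ConfusionMatrix.from_predictions(y_cv[test_idx], pred, positive)
        pooled = cm if pooled is None else pooled + cm
        try:
            fold_metrics.append(metrics_report(cm))
        except ZeroDivisionError:
            # tiny folds (leave-one-out) can miss a class entirely
            fold_metrics.append({"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn})

    auc = roc_auc(oof_scores, y_cv, positive)
    return CVResult(
        confusion=pooled,
        fold_metrics=fold_metrics,
        oof_scores=oof_scores[:n_original] if mode == "paper-mode" else oof_scores,
        oof_predictions=oof_pred[:n_original] if mode == "paper-mode" else oof_pred,
        y=y_cv,
        auc=auc,
        mode=mode,
        folds=folds,
    )


def save_model(clf: RandomForestClassifier, path) -> None:
    """Persist a trained classifier as a versioned binary artifact."""
    joblib.dump({"format_version": ARTIFACT_FORMAT_VERSION, "model": clf}, path)


def load_model(path) -> RandomForestClassifier:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != ARTIFACT_FORMAT_VERSION:
        raise ValueError(f"unsupported model artifact version {version!r}")
    return payload["model"]
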