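"""k-fold cross-validated evaluation: Acc/Sen/Spe, ROC and AUC.

AD is the positive class.  Sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), accuracy = (TP+TN)/total, all reported as percentages on the
confusion counts pooled over the k test folds (per-fold averages are also
kept).  Every data-dependent stage — activation mask, NMSE features, t-test
selection, reduction, LMNN and the classifier — is re-fit inside each
training fold, so no test-fold information leaks into model fitting.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .volume import POSITIVE_LABEL

__all__ = [
    "ConfusionCounts",
    "CVReport",
    "kfold_split",
    "metrics_from_counts",
    "roc_curve",
    "run_pipeline_cv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)

    @staticmethod
    def from_predictions(true: Sequence[int], pred: Sequence[int]) -> "ConfusionCounts":
        t = np.asarray(true, dtype=int)
        p = np.asarray(pred, dtype=int)
        pos = t == POSITIVE_LABEL
        return ConfusionCounts(
            TP=int(np.sum(pos & (p == POSITIVE_LABEL))),
            TN=int(np.sum(~pos & (p != POSITIVE_LABEL))),
            FP=int(np.sum(~pos & (p == POSITIVE_LABEL))),
            FN=int(np.sum(pos & (p != POSITIVE_LABEL))),
        )


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float | None]:
    """Acc/Sen/Spe percentages; an undefined metric (zero denominator) is
    reported as None, never silently as 0."""
    def ratio(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    return {
        "accuracy": ratio(c.TP + c.TN, c.total),
        "sensitivity": ratio(c.TP, c.TP + c.FN),
        "specificity": ratio(c.TN, c.TN + c.FP),
    }


def roc_curve(scores: Sequence[float], labels: Sequence[int]
              ) -> tuple[np.ndarray, float]:
    """(FPR, TPR) points from a threshold sweep plus the trapezoidal AUC.

    Higher score must mean "more AD-like"; tied scores step simultaneously.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, s, pos_label=POSITIVE_LABEL)
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


def kfold_split(n: int, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Random permutation of range(n) cut into k near-equal disjoint folds."""
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def stratified_kfold_split(labels: Sequence[int], k: int = 10,
                           seed: int = 0) -> list[np.ndarray]:
    """Random k folds preserving the class proportions per fold.

    Plain random folds systematically anti-correlate the training-fold and
    test-fold class balances; with n ~ 10² and a flexible pipeline that can
    bias pooled accuracy well below chance on signal-free data, so the
    stratified split is the evaluation default (``kfold_split`` remains for
    the plain variant).
    """
    y = np.asarray(labels, dtype=int)
    if k > len(y):
        raise ValueError(f"k={k} exceeds n={len(y)}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True,
                               random_state=int(seed) % (2 ** 32))
    return [np.sort(test) for _, test in splitter.split(np.zeros(len(y)), y)]


@dataclass
class CVReport:
    """Cross-validation outcome for one pipeline configuration."""

    pipeline_id: str
    seed: int
    per_fold: list[ConfusionCounts]
    pooled: ConfusionCounts
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    per_fold_mean: dict[str, float | None]
    roc_points: np.ndarray
    auc: float
    scores: np.ndarray
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    fold_model_hashes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pipeline_id": self.pipeline_id,
            "seed": self.seed,
            "per_fold": [vars(c) | {"metrics": metrics_from_counts(c)}
                         for c in self.per_fold],
            "pooled": vars(self.pooled),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "per_fold_mean": self.per_fold_mean,
            "auc": self.auc,
            "roc_points": self.roc_points.tolist(),
            "scores": self.scores.tolist(),
            "true_labels": self.true_labels.tolist(),
            "predicted_labels": self.predicted_labels.tolist(),
            "fold_model_hashes": self.fold_model_hashes,
        }


def _mean_or_none(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def hash_arrays(*arrays: np.ndarray) -> str:
    """Stable fingerprint of fitted-model parameters, for leakage checks."""
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(np.asarray(a, dtype=np.float64))
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()


def run_pipeline_cv(cohort, pipeline_config, seed: int,
                    max_redraws: int = 20) -> CVReport:
    """Run the configured pipeline under k-fold CV.

    The split is re-drawn (with a derived seed) if some training fold would
    miss a class; every stage is fit on the training fold only, then the
    held-out fold is scored.  Confusion counts are pooled over folds.
    """
    from .pipeline import fit_fold, pipeline_id  # local import: CLI layer sits above

    labels = np.array([rec.label for rec in cohort], dtype=int)
    n = len(cohort)
    k = pipeline_config.folds
    stratified = getattr(pipeline_config, "stratified_folds", True)
    split_seed = seed
    for attempt in range(max_redraws + 1):
        if stratified:
            folds = stratified_kfold_split(labels, k, seed=split_seed)
        else:
            folds = kfold_split(n, k, seed=split_seed)
        ok = all(len(np.unique(labels[np.setdiff1d(np.arange(n), f)])) == 2
                 for f in folds)
        if ok:
            break
        split_seed = (split_seed * 1_000_003 + 7919 + attempt) % (2 ** 31)
    else:
        raise RuntimeError(
            f"no class-complete {k}-fold split found after {max_redraws} redraws")

    per_fold: list[ConfusionCounts] = []
    fold_hashes: list[str] = []
    all_scores = np.empty(n)
    all_pred = np.empty(n, dtype=int)
    for fold in folds:
        train_idx = np.setdiff1d(np.arange(n), fold)
        model = fit_fold([cohort[i] for i in train_idx], pipeline_config, seed)
        pred, scores = model.predict([cohort[i] for i in fold])
        per_fold.append(ConfusionCounts.from_predictions(labels[fold], pred))
        fold_hashes.append(model.fingerprint())
        all_pred[fold] = pred
        all_scores[fold] = scores

    pooled = sum(per_fold, ConfusionCounts())
    pooled_metrics = metrics_from_counts(pooled)
    fold_metrics = [metrics_from_counts(c) for c in per_fold]
    per_fold_mean = {key: _mean_or_none([m[key] for m in fold_metrics])
                     for key in ("accuracy", "sensitivity", "specificity")}
    roc_points, auc_value = roc_curve(all_scores, labels)
    return CVReport(
        pipeline_id=pipeline_id(pipeline_config), seed=seed,
        per_fold=per_fold, pooled=pooled,
        accuracy=pooled_metrics["accuracy"],
        sensitivity=pooled_metrics["sensitivity"],
        specificity=pooled_metrics["specificity"],
        per_fold_mean=per_fold_mean,
        roc_points=roc_points, auc=auc_value,
        scores=all_scores, true_labels=labels, predicted_labels=all_pred,
        fold_model_hashes=fold_hashes,
    )
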