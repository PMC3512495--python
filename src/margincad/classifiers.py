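"""Classifiers on reduced / metric-transformed features.

Three families, matching how the learned large-margin metric is consumed:

* k-nearest neighbors under the Euclidean or a learned Mahalanobis metric
  (M = LᵀL: Mahalanobis kNN is exactly Euclidean kNN on L-transformed data);
* the energy-based classifier (EBC), which scores each candidate label by
  the LMNN-style energy of adopting it — distance to the k nearest
  same-label training points plus the hinge losses of the impostors this
  hypothetical placement creates in both directions;
* soft-margin kernel SVMs (linear / quadratic / polynomial / RBF), the
  large-margin counterpart operating on the same feature vectors.

Binary ties always resolve to the negative (CTRL) label: in a diagnosis
setting an uninformative case should not raise an alarm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .lmnn import LinearTransform, MahalanobisMetric, find_target_neighbors
from .volume import NEGATIVE_LABEL, POSITIVE_LABEL

__all__ = ["KnnClassifier", "EnergyClassifier", "SvmClassifier"]


def _vote(labels: np.ndarray, order: np.ndarray, k: int) -> tuple[int, float]:
    top = labels[order[:k]]
    votes_pos = int(np.sum(top == POSITIVE_LABEL))
    votes_neg = k - votes_pos
    score = (votes_pos - votes_neg) / k
    if votes_pos > votes_neg:
        label = POSITIVE_LABEL
    elif votes_neg > votes_pos:
        label = NEGATIVE_LABEL
    else:  # even-k tie: the single nearest neighbor decides
        label = int(labels[order[0]])
    return label, score


@dataclass
class KnnClassifier:
    """Majority-vote kNN; ``metric`` is 'euclidean' or a MahalanobisMetric."""

    k: int = 3
    metric: str | MahalanobisMetric = "euclidean"
    training_features: np.ndarray | None = None
    training_labels: np.ndarray | None = None
    _factor: np.ndarray | None = field(default=None, repr=False)

    def fit(self, X, labels: Sequence) -> "KnnClassifier":
        X = np.asarray(X, dtype=np.float64)
        if self.k > X.shape[0]:
            raise ValueError("k exceeds training set size")
        self.training_features = X
        self.training_labels = np.asarray(labels, dtype=int)
        if isinstance(self.metric, MahalanobisMetric):
            # factor M = FᵀF via eigendecomposition (PSD up to rounding)
            w, V = np.linalg.eigh(self.metric.M)
            w = np.clip(w, 0.0, None)
            self._factor = (V * np.sqrt(w)) @ V.T
        return self

    def _embed(self, X: np.ndarray) -> np.ndarray:
        if self._factor is not None:
            return X @ self._factor.T
        return X

    def predict(self, x) -> tuple[int, float]:
        """(label, score); score = (votes₊ − votes₋)/k, suitable for ROC."""
        if self.training_features is None:
            raise RuntimeError("classifier not fitted")
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        Zt = self._embed(self.training_features)
        Zx = self._embed(x)
        D = cdist(Zx, Zt, metric="sqeuclidean")
        out = [_vote(self.training_labels, np.argsort(row, kind="stable"), self.k)
               for row in D]
        return out[0] if len(out) == 1 else out  # type: ignore[return-value]

    def predict_batch(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        results = [self.predict(row) for row in X]
        labels = np.array([r[0] for r in results], dtype=int)
        scores = np.array([r[1] for r in results], dtype=float)
        return labels, scores


@dataclass
class EnergyClassifier:
    """Energy-based classification under a learned transform L.

    For a query x and candidate label ŷ the energy is the sum of three
    terms: (1) squared distances from x to its k nearest training points of
    label ŷ (its hypothetical target neighbors, chosen in L-space); (2) the
    hinge losses of differently labeled training points invading the margin
    around x set by those targets; (3) the hinge losses incurred where x
    itself invades the margins of training points labeled differently from
    ŷ.  The predicted label minimizes the energy; ties go to CTRL.
    """

    transform: LinearTransform
    k_targets: int = 3
    margin: float = 1.0
    training_features: np.ndarray | None = None
    training_labels: np.ndarray | None = None
    _Z: np.ndarray | None = field(default=None, repr=False)
    _train_target_d: np.ndarray | None = field(default=None, repr=False)

    def fit(self, X, labels: Sequence) -> "EnergyClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(labels, dtype=int)
        counts = {int(c): int(n) for c, n in zip(*np.unique(y, return_counts=True))}
        for cls, n in counts.items():
            if n <= self.k_targets:
                raise ValueError(
                    f"class {cls} has {n} members; needs > k={self.k_targets}")
        self.training_features = X
        self.training_labels = y
        self._Z = self.transform.transform(X)
        ns = find_target_neighbors(X, y, self.k_targets)
        D = cdist(self._Z, self._Z, metric="sqeuclidean")
        rows = np.repeat(np.arange(len(y)), self.k_targets)
        cols = ns.target_neighbors.ravel()
        self._train_target_d = D[rows, cols].reshape(len(y), self.k_targets)
        return self

    def _energy(self, zx: np.ndarray, candidate: int) -> float:
        y = self.training_labels
        d = np.sum((self._Z - zx) ** 2, axis=1)        # distances x ↔ training
        same = np.flatnonzero(y == candidate)
        other = np.flatnonzero(y != candidate)
        targets = same[np.argsort(d[same], kind="stable")[: self.k_targets]]
        term1 = float(d[targets].sum())
        # impostors entering the perimeter of x
        term2 = float(np.maximum(
            self.margin + d[targets][:, None] - d[other][None, :], 0.0).sum())
        # x entering the perimeters of differently labeled training points
        term3 = float(np.maximum(
            self.margin + self._train_target_d[other] - d[other][:, None], 0.0).sum())
        return term1 + term2 + term3

    def predict(self, x) -> tuple[int, float]:
        """(label, energy_gap); gap = energy(other) − energy(chosen) ≥ 0."""
        if self.training_features is None:
            raise RuntimeError("classifier not fitted")
        zx = self.transform.transform(np.asarray(x, dtype=np.float64))
        e_neg = self._energy(zx, NEGATIVE_LABEL)
        e_pos = self._energy(zx, POSITIVE_LABEL)
        if e_pos < e_neg:
            return POSITIVE_LABEL, e_neg - e_pos
        return NEGATIVE_LABEL, e_pos - e_neg

    def predict_batch(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Labels plus signed scores (energy advantage of the AD label)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        labels, scores = [], []
        for row in X:
            zx = self.transform.transform(row)
            e_neg = self._energy(zx, NEGATIVE_LABEL)
            e_pos = self._energy(zx, POSITIVE_LABEL)
            labels.append(POSITIVE_LABEL if e_pos < e_neg else NEGATIVE_LABEL)
            scores.append(e_neg - e_pos)
        return np.asarray(labels, dtype=int), np.asarray(scores, dtype=float)


_KERNELS = {
    "linear": dict(kernel="linear"),
    "quadratic": dict(kernel="poly", degree=2),
    "polynomial": dict(kernel="poly", degree=3),
    "rbf": dict(kernel="rbf"),
}


@dataclass
class SvmClassifier:
    """Soft-margin kernel SVM (dual, via scikit-learn's SVC)."""

    kernel: str = "linear"
    C: float = 1.0
    degree: int | None = None
    gamma: float | str = "scale"
    _svc: SVC | None = field(default=None, repr=False)

    def fit(self, X, labels: Sequence) -> "SvmClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("SVM training requires both classes")
        if self.kernel not in _KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        params = dict(_KERNELS[self.kernel])
        if self.degree is not None and params.get("kernel") == "poly":
            params["degree"] = self.degree
        self._svc = SVC(C=self.C, gamma=self.gamma, coef0=1.0, **params)
        self._svc.fit(X, y)
        return self

    def predict(self, x) -> tuple[int, float]:
        """(label, margin): signed decision value; 0 resolves to CTRL."""
        if self._svc is None:
            raise RuntimeError("classifier not fitted")
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        m = float(self._svc.decision_function(x)[0])
        return (POSITIVE_LABEL if m > 0 else NEGATIVE_LABEL), m

    def predict_batch(self, X) -> tuple[np.ndarray, np.ndarray]:
        if self._svc is None:
            raise RuntimeError("classifier not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        margins = self._svc.decision_function(X)
        labels = np.where(margins > 0, POSITIVE_LABEL, NEGATIVE_LABEL)
        return labels.astype(int), np.asarray(margins, dtype=float)
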