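"""Large-margin nearest-neighbor (LMNN) metric learning.

LMNN learns a linear transform L whose induced squared distance

    D_L(x_i, x_j) = ‖L (x_i − x_j)‖²  =  (x_i − x_j)ᵀ M (x_i − x_j),   M = LᵀL

pulls each sample toward its k same-class *target neighbors* and pushes
differently labeled *impostors* out of a unit margin around them.  The loss

    ε(L) = (1 − μ) Σ_{j→i} D_L(x_i, x_j)
         + μ Σ_{i, j→i} Σ_l (1 − y_il) [1 + D_L(x_i, x_j) − D_L(x_i, x_l)]₊

is minimized by gradient descent directly over L.  Optimizing over L (rather
than over the PSD matrix M) is non-convex but allows a *rectangular* L with
r < d rows, in which case LMNN doubles as a supervised dimensionality
reducer (LMNN-RECT).  Run on kernel-PCA coordinates the same machinery
yields the kernelized variant (KLMNN).

Target neighbors are chosen once, by Euclidean distance in the input space,
and stay fixed for the whole optimization; impostor (hinge-active) triplets
are re-scanned every iteration, which is exact and affordable at cohort
sizes of ~10²  samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "LinearTransform",
    "MahalanobisMetric",
    "LmnnConfig",
    "NeighborStructure",
    "find_target_neighbors",
    "squared_distance_L",
    "lmnn_loss",
    "lmnn_gradient",
    "optimize_L",
    "make_mahalanobis",
    "fit_klmnn",
]


@dataclass
class LinearTransform:
    """An r × d transform; r = d for the square metric, r < d for LMNN-RECT."""

    L: np.ndarray

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=np.float64)
        if self.L.ndim != 2:
            raise ValueError("L must be a matrix")
        if self.L.shape[0] > self.L.shape[1]:
            raise ValueError("output dimension r must not exceed input dimension d")
        if not np.all(np.isfinite(self.L)):
            raise ValueError("L contains non-finite entries")

    @property
    def input_dim(self) -> int:
        return self.L.shape[1]

    @property
    def output_dim(self) -> int:
        return self.L.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64) @ self.L.T


@dataclass
class MahalanobisMetric:
    """M = LᵀL; symmetric PSD by construction."""

    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.float64)
        if self.M.ndim != 2 or self.M.shape[0] != self.M.shape[1]:
            raise ValueError("M must be square")
        if np.max(np.abs(self.M - self.M.T)) > 1e-10:
            raise ValueError("M must be symmetric")

    def squared_distance(self, xi: np.ndarray, xj: np.ndarray) -> float:
        d = np.asarray(xi, dtype=np.float64) - np.asarray(xj, dtype=np.float64)
        return float(d @ self.M @ d)


@dataclass
class LmnnConfig:
    """Optimization settings; μ balances the pull and push terms."""

    k_targets: int = 3
    mu: float = 0.5
    max_iter: int = 200
    step_init: float = 1e-3
    tol: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.k_targets < 1:
            raise ValueError("k_targets must be >= 1")


@dataclass
class NeighborStructure:
    """Fixed per-sample target-neighbor lists (same class, no self)."""

    target_neighbors: np.ndarray  # (n, k) indices
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.target_neighbors = np.asarray(self.target_neighbors, dtype=np.intp)
        self.labels = np.asarray(self.labels)

    @property
    def k(self) -> int:
        return self.target_neighbors.shape[1]


def find_target_neighbors(X, labels: Sequence, k: int) -> NeighborStructure:
    """k nearest same-class samples per sample (Euclidean, input space),
    self excluded by index so exact duplicates remain eligible."""
    Xm = np.asarray(X, dtype=np.float64)
    y = np.asarray(labels)
    n = Xm.shape[0]
    targets = np.empty((n, k), dtype=np.intp)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) <= k:
            raise ValueError(
                f"class {cls!r} has {len(idx)} members; needs > k={k}")
        D = cdist(Xm[idx], Xm[idx], metric="sqeuclidean")
        np.fill_diagonal(D, np.inf)
        order = np.argsort(D, axis=1, kind="stable")[:, :k]
        targets[idx] = idx[order]
    return NeighborStructure(target_neighbors=targets, labels=y)


def squared_distance_L(L: LinearTransform, xi, xj) -> float:
    """‖L(x_i − x_j)‖²."""
    xi = np.asarray(xi, dtype=np.float64)
    xj = np.asarray(xj, dtype=np.float64)
    if xi.shape != xj.shape or xi.shape[-1] != L.input_dim:
        raise ValueError("dimension mismatch")
    z = L.L @ (xi - xj)
    return float(z @ z)


def _pair_and_impostor_terms(L: np.ndarray, X: np.ndarray,
                             ns: NeighborStructure):
    """Shared geometry: projected distances for target pairs and the hinge
    margins against all differently labeled points."""
    Z = X @ L.T
    n, k = ns.target_neighbors.shape
    D = cdist(Z, Z, metric="sqeuclidean")              # (n, n)
    rows = np.repeat(np.arange(n), k)
    cols = ns.target_neighbors.ravel()
    d_target = D[rows, cols].reshape(n, k)             # (n, k)
    diff = ns.labels[:, None] != ns.labels[None, :]    # (n, n) 1 − y_il
    # margins[i, j, l] = 1 + D[i, target_j] − D[i, l], only where labels differ
    margins = 1.0 + d_target[:, :, None] - D[:, None, :]
    margins *= diff[:, None, :]
    return Z, D, d_target, diff, margins


def lmnn_loss(L: LinearTransform, X, ns: NeighborStructure,
              mu: float) -> tuple[float, float, float]:
    """(total, pull, push): total = (1 − μ)·pull + μ·push."""
    Xm = np.asarray(X, dtype=np.float64)
    _, _, d_target, diff, margins = _pair_and_impostor_terms(L.L, Xm, ns)
    pull = float(d_target.sum())
    push = float(np.maximum(margins, 0.0)[:, :, :].sum()
                 ) if diff.any() else 0.0
    total = (1.0 - mu) * pull + mu * push
    return total, pull, push


def lmnn_gradient(L: LinearTransform, X, ns: NeighborStructure,
                  mu: float) -> np.ndarray:
    """Analytic gradient of the loss w.r.t. L (subgradient 0 at hinge kinks).

    ∂pull/∂L = 2 L Σ_{j→i} C_ij  with C_ij = (x_i−x_j)(x_i−x_j)ᵀ;
    ∂push/∂L = 2 L Σ_{active (i,j,l)} (C_ij − C_il), where a triplet is
    active when its hinge argument is strictly positive.
    """
    Xm = np.asarray(X, dtype=np.float64)
    n, k = ns.target_neighbors.shape
    _, _, _, diff, margins = _pair_and_impostor_terms(L.L, Xm, ns)
    active = margins > 0                                   # (n, k, n)
    active &= diff[:, None, :]

    rows = np.repeat(np.arange(n), k)
    cols = ns.target_neighbors.ravel()
    pair_diffs = Xm[rows] - Xm[cols]                       # (n·k, d)
    C_pull = pair_diffs.T @ pair_diffs                     # Σ C_ij

    # pair multiplicities: for each target pair, # active impostors
    pair_counts = active.sum(axis=2).ravel().astype(np.float64)   # (n·k,)
    C_push_pairs = (pair_diffs * pair_counts[:, None]).T @ pair_diffs
    # impostor multiplicities: for each (i, l), # active target pairs
    il_counts = active.sum(axis=1).astype(np.float64)      # (n, n)
    # Σ_{i,l} c_il (x_i − x_l)(x_i − x_l)ᵀ expanded into three Gram pieces
    ci = il_counts.sum(axis=1)
    cl = il_counts.sum(axis=0)
    C_push_il = ((Xm * ci[:, None]).T @ Xm + (Xm * cl[:, None]).T @ Xm
                 - Xm.T @ il_counts @ Xm - (il_counts @ Xm).T @ Xm)

    grad = 2.0 * L.L @ ((1.0 - mu) * C_pull + mu * (C_push_pairs - C_push_il))
    return grad


def _initial_transform(X: np.ndarray, output_dim: int) -> np.ndarray:
    d = X.shape[1]
    if output_dim == d:
        return np.eye(d)
    # rectangular start: rows are the top-r principal directions of X
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    return Vt[:output_dim].copy()


def optimize_L(X, labels: Sequence, config: LmnnConfig,
               output_dim: int | None = None
               ) -> tuple[LinearTransform, np.ndarray]:
    """Gradient descent over L with an adaptive step size.

    A step that lowers the loss is accepted and the step grows ×1.1; a step
    that raises it is reverted and the step shrinks ×0.5.  Terminates when
    the relative change of accepted losses drops below ``tol`` or after
    ``max_iter`` iterations.  Returns the transform and the accepted-iterate
    loss trace (non-increasing by construction).
    """
    Xm = np.asarray(X, dtype=np.float64)
    n, d = Xm.shape
    if output_dim is None:
        output_dim = d
    if not 1 <= output_dim <= d:
        raise ValueError(f"output_dim must be in [1, {d}]")
    ns = find_target_neighbors(Xm, labels, config.k_targets)
    L = _initial_transform(Xm, output_dim)
    lt = LinearTransform(L)
    loss, _, _ = lmnn_loss(lt, Xm, ns, config.mu)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite initial LMNN loss")
    trace = [loss]
    step = config.step_init
    for _ in range(config.max_iter):
        grad = lmnn_gradient(lt, Xm, ns, config.mu)
        gnorm = float(np.linalg.norm(grad))
        if gnorm == 0.0:
            break
        candidate = LinearTransform(lt.L - step * grad)
        cand_loss, _, _ = lmnn_loss(candidate, Xm, ns, config.mu)
        if not np.isfinite(cand_loss):
            raise FloatingPointError("non-finite LMNN loss during optimization")
        if cand_loss < loss:
            rel = (loss - cand_loss) / max(abs(loss), 1e-30)
            lt = candidate
            loss = cand_loss
            trace.append(loss)
            step *= 1.1
            if rel < config.tol:
                break
        else:
            step *= 0.5
            if step < 1e-18:
                break
    return lt, np.asarray(trace)


def make_mahalanobis(L: LinearTransform) -> MahalanobisMetric:
    """M = LᵀL (symmetrized against rounding)."""
    M = L.L.T @ L.L
    return MahalanobisMetric(M=(M + M.T) / 2.0)


def fit_klmnn(X, labels: Sequence, config: LmnnConfig, kpca
              ) -> tuple[LinearTransform, np.ndarray]:
    """Kernel LMNN via the KPCA trick: optimize L on kernel-PCA coordinates.

    The composite map x ↦ L·kpca(x) is the learned kernel metric; classify
    by projecting new points through the same KpcaModel first.
    """
    from .reduction import project
    Z = project(kpca, np.asarray(X, dtype=np.float64))
    return optimize_L(Z, labels, config, output_dim=None)
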