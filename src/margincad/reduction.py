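"""Dimensionality reduction: PCA, Gaussian-kernel PCA, and SIMPLS PLS.

The cohorts are tiny relative to the feature count (the small-sample-size
problem), so the ~200 t-test-selected NMSE features are reduced to a handful
of components before metric learning and classification:

* **PCA** — eigendecomposition of the sample covariance of the centered
  feature matrix; unsupervised variance-maximizing directions.
* **Kernel PCA** — PCA in the feature space induced by a Gaussian kernel
  k(x, y) = exp(−‖x−y‖²/(2σ²)); solved in the dual with explicit
  double-centering of the kernel matrix.  With a linear kernel it reproduces
  PCA scores exactly, which the test suite uses as a cross-check.
* **PLS via SIMPLS** — supervised latent components maximizing covariance
  with the class label; SIMPLS deflates the cross-product matrix S = XᵀY
  instead of the data matrices.

``variance_explained`` supports the usual model-selection plot (components
vs. percent variance); the pipelines default to 6 components, past which the
explained variance flattens out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .nmse import FeatureMatrix

__all__ = [
    "PcaModel",
    "KpcaModel",
    "PlsModel",
    "KernelPlsModel",
    "fit_pca",
    "fit_kpca",
    "fit_pls_simpls",
    "fit_kernel_pls",
    "project",
    "variance_explained",
]


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=np.float64)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|.| entry of each column > 0."""
    vectors = vectors.copy()
    for j in range(vectors.shape[1]):
        i = int(np.argmax(np.abs(vectors[:, j])))
        if vectors[i, j] < 0:
            vectors[:, j] = -vectors[:, j]
    return vectors


@dataclass
class PcaModel:
    mean_vector: np.ndarray
    components: np.ndarray          # features × n_components, orthonormal
    eigenvalues: np.ndarray         # descending, for kept components
    total_variance: float           # trace of the sample covariance

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass
class KpcaModel:
    training_inputs: np.ndarray     # retained sample matrix (n × d)
    alpha: np.ndarray               # dual coefficients (n × n_components)
    sigma: float | None             # Gaussian width; None for the linear kernel
    k_row_means: np.ndarray         # per-training-sample kernel row mean
    k_grand_mean: float
    eigenvalues: np.ndarray         # of the centered kernel matrix, descending
    kernel: str = "rbf"

    @property
    def n_components(self) -> int:
        return self.alpha.shape[1]

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            return A @ B.T
        sq = (np.sum(A * A, axis=1)[:, None] + np.sum(B * B, axis=1)[None, :]
              - 2.0 * A @ B.T)
        np.maximum(sq, 0.0, out=sq)
        return np.exp(-sq / (2.0 * self.sigma ** 2))


@dataclass
class PlsModel:
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray             # W: features × n_components, unit-norm columns
    scores: np.ndarray              # T: samples × n_components, unit-norm columns
    loadings: np.ndarray            # P: features × n_components
    x_rotation: np.ndarray = field(default=None)  # type: ignore[assignment]
    total_variance: float = 0.0     # ‖X_c‖_F² of the training data

    def __post_init__(self) -> None:
        if self.x_rotation is None:
            self.x_rotation = self.weights

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]


@dataclass
class KernelPlsModel:
    """Gaussian-kernel PLS realized as SIMPLS on kernel-PCA coordinates."""

    kpca: KpcaModel
    pls: PlsModel

    @property
    def n_components(self) -> int:
        return self.pls.n_components


def fit_pca(X, n_components: int) -> PcaModel:
    """PCA by SVD of the centered data; eigenvalues are those of the sample
    covariance (ddof=1)."""
    Xm = _as_matrix(X)
    n, d = Xm.shape
    max_comp = min(n - 1, d)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, {max_comp}] for {n} samples × {d} features")
    mean = Xm.mean(axis=0)
    Xc = Xm - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s ** 2 / (n - 1)
    components = _fix_signs(Vt[:n_components].T)
    return PcaModel(mean_vector=mean, components=components,
                    eigenvalues=eigenvalues[:n_components],
                    total_variance=float(eigenvalues.sum()))


def median_pairwise_distance(X) -> float:
    """Default Gaussian kernel width: median of pairwise training distances."""
    Xm = _as_matrix(X)
    sq = (np.sum(Xm * Xm, axis=1)[:, None] + np.sum(Xm * Xm, axis=1)[None, :]
          - 2.0 * Xm @ Xm.T)
    np.maximum(sq, 0.0, out=sq)
    d = np.sqrt(sq[np.triu_indices_from(sq, k=1)])
    med = float(np.median(d)) if d.size else 1.0
    return med if med > 0 else 1.0


def fit_kpca(X, n_components: int, sigma: float | None = None,
             kernel: str = "rbf") -> KpcaModel:
    """Kernel PCA with explicit double-centering of the kernel matrix.

    Dual coefficients are scaled as v/√λ so projections of the training data
    coincide with the scores of linear PCA when ``kernel='linear'`` (and more
    generally are the principal-component scores in feature space).
    """
    Xm = _as_matrix(X)
    if kernel not in ("rbf", "linear"):
        raise ValueError(f"unknown kernel {kernel!r}")
    if kernel == "rbf":
        if sigma is None:
            sigma = median_pairwise_distance(Xm)
        if sigma <= 0:
            raise ValueError("sigma must be positive")
    n = Xm.shape[0]
    if not 1 <= n_components <= n - 1:
        raise ValueError(f"n_components must be in [1, {n - 1}]")
    model = KpcaModel(training_inputs=Xm, alpha=np.empty((n, 0)), sigma=sigma,
                      k_row_means=np.zeros(n), k_grand_mean=0.0,
                      eigenvalues=np.empty(0), kernel=kernel)
    K = model._kernel(Xm, Xm)
    row_means = K.mean(axis=1)
    grand = float(K.mean())
    Kc = K - row_means[:, None] - row_means[None, :] + grand
    evals, evecs = np.linalg.eigh(Kc)
    order = np.argsort(evals)[::-1][:n_components]
    evals = evals[order]
    evecs = evecs[:, order]
    if np.any(evals <= 1e-12 * max(evals.max(), 1.0)):
        raise ValueError("requested components beyond the numerical rank of K")
    alpha = _fix_signs(evecs / np.sqrt(evals))
    model.alpha = alpha
    model.k_row_means = row_means
    model.k_grand_mean = grand
    model.eigenvalues = evals
    return model


def fit_pls_simpls(X, Y, n_components: int) -> PlsModel:
    """SIMPLS partial least squares.

    S₀ = XᵀY on centered data; each step deflates S by projecting out the
    accumulated loadings P, takes the weight w_j as the first left singular
    vector of S_j, forms the unit-norm score t_j = X w_j / ‖X w_j‖ and the
    loading p_j = Xᵀ t_j.  Deflation acts on S only — X and Y are never
    deflated.  Stops early (with a warning) if S deflates to zero.
    """
    Xm = _as_matrix(X)
    if isinstance(Y, FeatureMatrix):
        Y = Y.values
    Ym = np.asarray(Y, dtype=np.float64)
    if Ym.ndim == 1:
        Ym = Ym[:, None]
    n, d = Xm.shape
    if Ym.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if not 1 <= n_components <= min(n - 1, d):
        raise ValueError(f"n_components must be in [1, {min(n - 1, d)}]")
    x_mean = Xm.mean(axis=0)
    y_mean = Ym.mean(axis=0)
    Xc = Xm - x_mean
    Yc = Ym - y_mean

    S = Xc.T @ Yc
    s_scale = float(np.linalg.norm(S))
    W_cols, T_cols, P_cols, R_cols = [], [], [], []
    for j in range(n_components):
        if P_cols:
            P = np.column_stack(P_cols)
            S = S - P @ np.linalg.solve(P.T @ P, P.T @ S)
        if np.linalg.norm(S) <= 1e-12 * max(s_scale, 1.0):
            warnings.warn(
                f"SIMPLS stopped after {j} components: cross-product matrix "
                "fully deflated", RuntimeWarning)
            break
        U, _, _ = np.linalg.svd(S, full_matrices=False)
        w = U[:, 0]
        w = w / np.linalg.norm(w)
        t_raw = Xc @ w
        t_norm = float(np.linalg.norm(t_raw))
        if t_norm <= 0:
            warnings.warn(f"SIMPLS stopped after {j} components: zero score",
                          RuntimeWarning)
            break
        t = t_raw / t_norm
        p = Xc.T @ t
        W_cols.append(w)
        T_cols.append(t)
        P_cols.append(p)
        R_cols.append(w / t_norm)  # rotation reproducing the unit-norm scores
    if not W_cols:
        raise ValueError("labels carry no signal: S is zero at the first step")
    W = np.column_stack(W_cols)
    sign = np.array([1.0 if W[np.argmax(np.abs(W[:, j])), j] > 0 else -1.0
                     for j in range(W.shape[1])])
    return PlsModel(x_mean=x_mean, y_mean=y_mean,
                    weights=W * sign,
                    scores=np.column_stack(T_cols) * sign,
                    loadings=np.column_stack(P_cols) * sign,
                    x_rotation=np.column_stack(R_cols) * sign,
                    total_variance=float(np.sum(Xc * Xc)))


def fit_kernel_pls(X, Y, n_components: int, sigma: float | None = None,
                   n_kpca_components: int | None = None) -> KernelPlsModel:
    """Gaussian-kernel PLS via the KPCA trick: map to kernel-PCA coordinates,
    then run SIMPLS there."""
    Xm = _as_matrix(X)
    n = Xm.shape[0]
    if n_kpca_components is None:
        n_kpca_components = min(n - 1, max(n_components, min(n - 1, 2 * n_components)))
    kpca = fit_kpca(Xm, n_components=n_kpca_components, sigma=sigma)
    Z = project(kpca, Xm)
    pls = fit_pls_simpls(Z, Y, n_components)
    return KernelPlsModel(kpca=kpca, pls=pls)


AnyModel = Union[PcaModel, KpcaModel, PlsModel, KernelPlsModel]


def project(model: AnyModel, X_new) -> np.ndarray:
    """Map new samples to component coordinates of a fitted model."""
    Xm = _as_matrix(X_new)
    single = Xm.ndim == 1
    if single:
        Xm = Xm[None, :]
    if isinstance(model, PcaModel):
        if Xm.shape[1] != model.mean_vector.shape[0]:
            raise ValueError("feature dimension mismatch")
        out = (Xm - model.mean_vector) @ model.components
    elif isinstance(model, KpcaModel):
        if Xm.shape[1] != model.training_inputs.shape[1]:
            raise ValueError("feature dimension mismatch")
        k = model._kernel(Xm, model.training_inputs)          # (m × n)
        kc = (k - k.mean(axis=1, keepdims=True)
              - model.k_row_means[None, :] + model.k_grand_mean)
        out = kc @ model.alpha
    elif isinstance(model, PlsModel):
        if Xm.shape[1] != model.x_mean.shape[0]:
            raise ValueError("feature dimension mismatch")
        # unit-norm weight columns: later (noise-dominated) components keep
        # their natural small scale instead of being inflated to unit-norm
        # scores, which matters for everything consuming the coordinates
        out = (Xm - model.x_mean) @ model.weights
    elif isinstance(model, KernelPlsModel):
        out = project(model.pls, project(model.kpca, Xm))
    else:
        raise TypeError(f"cannot project through {type(model).__name__}")
    return out[0] if single else out


def variance_explained(model: PcaModel | PlsModel | KernelPlsModel) -> np.ndarray:
    """Percentage of the total training X variance captured per component."""
    if isinstance(model, PcaModel):
        return 100.0 * model.eigenvalues / model.total_variance
    if isinstance(model, KernelPlsModel):
        model = model.pls
    if isinstance(model, PlsModel):
        # scores are unit-norm, so the rank-1 reconstruction t_j p_jᵀ has
        # squared Frobenius norm ‖p_j‖²
        if model.total_variance <= 0:
            return np.zeros(model.n_components)
        return 100.0 * np.sum(model.loadings ** 2, axis=0) / model.total_variance
    raise TypeError(f"variance_explained undefined for {type(model).__name__}")
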