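"""End-to-end pipeline configuration and per-fold fitting.

A PipelineConfig names one cell of the study grid: intensity normalization
(SPECT or PET rule), NMSE block side, number of t-test-selected blocks,
reduction method and component count, whether a square LMNN transform is
applied to the reduced coordinates, and the final classifier.  LMNN-RECT is
itself the reduction, so it excludes both a second reduction technique and
the extra square transform.

``fit_fold`` fits every stage on a training cohort only and returns a
FoldModel that can score held-out subjects — the unit of work that
``evaluation.run_pipeline_cv`` repeats per fold.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import reduction as red
from .classifiers import EnergyClassifier, KnnClassifier, SvmClassifier
from .evaluation import hash_arrays
from .lmnn import LinearTransform, LmnnConfig, make_mahalanobis, optimize_L
from .nmse import (FeatureMatrix, build_block_grid, nmse_feature_matrix,
                   select_features, ttest_rank)
from .volume import (SubjectRecord, compute_activation_mask,
                     mean_control_volume, normalize_intensity_pet,
                     normalize_intensity_spect)

__all__ = ["PipelineConfig", "FoldModel", "fit_fold", "pipeline_id", "run"]

REDUCTIONS = ("pca", "kpca", "pls", "kernel_pls", "lmnn_rect", "none")
CLASSIFIERS = ("svm_linear", "svm_quadratic", "svm_poly", "svm_rbf",
               "knn_euclidean", "knn_mahalanobis", "ebc")
NORMALIZATIONS = ("spect", "pet", "none")


@dataclass
class PipelineConfig:
    normalization: str = "spect"
    block_side: int = 5
    n_select: int = 200
    reduction: str = "pls"
    n_components: int = 6
    lmnn_transform: bool = True
    classifier: str = "svm_linear"
    lmnn: LmnnConfig = field(default_factory=LmnnConfig)
    knn_k: int = 3
    kpca_sigma: float | None = None
    folds: int = 10
    stratified_folds: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.reduction not in REDUCTIONS:
            raise ValueError(f"unknown reduction {self.reduction!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.block_side % 2 == 0 or self.block_side < 3:
            raise ValueError("block_side must be odd and >= 3")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.reduction == "lmnn_rect" and self.lmnn_transform:
            raise ValueError(
                "lmnn_rect is itself the reduction; it excludes the extra "
                "square LMNN transform")
        needs_metric = self.classifier in ("knn_mahalanobis", "ebc")
        if needs_metric and not (self.lmnn_transform or self.reduction == "lmnn_rect"):
            raise ValueError(
                f"classifier {self.classifier!r} needs a learned transform; "
                "enable lmnn_transform or use lmnn_rect")

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        payload.pop("schema_version", None)
        lmnn_payload = payload.pop("lmnn", None)
        known = set(cls.__dataclass_fields__)  # type: ignore[attr-defined]
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        if lmnn_payload is not None:
            unknown = set(lmnn_payload) - set(LmnnConfig.__dataclass_fields__)
            if unknown:
                raise ValueError(f"unknown lmnn config keys: {sorted(unknown)}")
            cfg.lmnn = LmnnConfig(**lmnn_payload)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = 1
        return d


def pipeline_id(config: PipelineConfig) -> str:
    parts = ["nmse", config.reduction]
    if config.lmnn_transform:
        parts.append("lmnn")
    parts.append(config.classifier)
    return "-".join(parts)


def _normalize(rec: SubjectRecord, how: str) -> SubjectRecord:
    if how == "spect":
        vol = normalize_intensity_spect(rec.volume)
    elif how == "pet":
        vol = normalize_intensity_pet(rec.volume)
    else:
        vol = rec.volume
    return SubjectRecord(subject_id=rec.subject_id, label=rec.label,
                         volume=vol, severity=rec.severity)


@dataclass
class FoldModel:
    """Everything fitted on one training fold."""

    config: PipelineConfig
    mean_control: np.ndarray
    mask_threshold: float
    grid_centers: np.ndarray
    grid_side: int
    selected: list
    reducer: object | None
    transform: LinearTransform | None
    classifier: object
    mean_control_volume: object = None

    def _features(self, cohort: Sequence[SubjectRecord]) -> np.ndarray:
        from .nmse import BlockGrid
        from .volume import BrainVolume

        cohort = [_normalize(r, self.config.normalization) for r in cohort]
        f = BrainVolume(self.mean_control)
        grid = BlockGrid(centers=self.grid_centers, side=self.grid_side)
        fm = nmse_feature_matrix(cohort, f, grid)
        fm = select_features(fm, self.selected)
        X = fm.values
        if self.reducer is not None:
            X = red.project(self.reducer, X)
        if self.transform is not None:
            X = self.transform.transform(X)
        return X

    def predict(self, cohort: Sequence[SubjectRecord]
                ) -> tuple[np.ndarray, np.ndarray]:
        X = self._features(cohort)
        return self.classifier.predict_batch(X)

    def fingerprint(self) -> str:
        """Hash of every fitted parameter, for leakage tests."""
        arrays = [self.mean_control, np.array([self.mask_threshold]),
                  self.grid_centers.astype(float),
                  np.array([[*s.center, s.t_abs] if isinstance(s.center, tuple)
                            else [s.center, 0, 0, s.t_abs]
                            for s in self.selected], dtype=float)]
        r = self.reducer
        if isinstance(r, red.PcaModel):
            arrays += [r.mean_vector, r.components, r.eigenvalues]
        elif isinstance(r, red.KpcaModel):
            arrays += [r.training_inputs, r.alpha, r.k_row_means]
        elif isinstance(r, red.PlsModel):
            arrays += [r.x_mean, r.weights, r.x_rotation]
        elif isinstance(r, red.KernelPlsModel):
            arrays += [r.kpca.training_inputs, r.kpca.alpha,
                       r.pls.x_mean, r.pls.x_rotation]
        if self.transform is not None:
            arrays.append(self.transform.L)
        clf = self.classifier
        if isinstance(clf, SvmClassifier):
            arrays += [clf._svc.dual_coef_, clf._svc.support_vectors_,
                       clf._svc.intercept_]
        elif isinstance(clf, KnnClassifier):
            arrays += [clf.training_features, clf.training_labels]
            if not isinstance(clf.metric, str):
                arrays.append(clf.metric.M)
        elif isinstance(clf, EnergyClassifier):
            arrays += [clf.training_features, clf.training_labels,
                       clf.transform.L]
        return hash_arrays(*arrays)


def fit_fold(train: Sequence[SubjectRecord], config: PipelineConfig,
             seed: int) -> FoldModel:
    """Fit mask → NMSE → t-test → reduction → LMNN → classifier on the
    training subjects only."""
    train = [_normalize(r, config.normalization) for r in train]
    labels = np.array([r.label for r in train], dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training fold must contain both classes")

    f = mean_control_volume(train)
    mask = compute_activation_mask(f)
    grid = build_block_grid(mask, side=config.block_side)
    fm = nmse_feature_matrix(train, f, grid)
    n_select = min(config.n_select, fm.n_features)
    scores = ttest_rank(fm, n_select=n_select)
    fm_sel = select_features(fm, scores)

    X = fm_sel.values
    reducer = None
    transform = None
    lmnn_cfg = config.lmnn

    if config.reduction == "pca":
        reducer = red.fit_pca(X, config.n_components)
    elif config.reduction == "kpca":
        reducer = red.fit_kpca(X, config.n_components, sigma=config.kpca_sigma)
    elif config.reduction == "pls":
        y_pm = np.where(labels == 1, 1.0, -1.0)
        reducer = red.fit_pls_simpls(X, y_pm, config.n_components)
    elif config.reduction == "kernel_pls":
        y_pm = np.where(labels == 1, 1.0, -1.0)
        reducer = red.fit_kernel_pls(X, y_pm, config.n_components,
                                     sigma=config.kpca_sigma)
    elif config.reduction == "lmnn_rect":
        transform, _ = optimize_L(X, labels, lmnn_cfg,
                                  output_dim=config.n_components)
    # "none": raw selected NMSE features

    Z = X if reducer is None else red.project(reducer, X)
    if config.lmnn_transform:
        transform, _ = optimize_L(Z, labels, lmnn_cfg, output_dim=None)
    Zt = Z if transform is None else transform.transform(Z)

    if config.classifier.startswith("svm_"):
        kernel = {"svm_linear": "linear", "svm_quadratic": "quadratic",
                  "svm_poly": "polynomial", "svm_rbf": "rbf"}[config.classifier]
        clf = SvmClassifier(kernel=kernel).fit(Zt, labels)
        clf_input_transform = None
    elif config.classifier == "knn_euclidean":
        clf = KnnClassifier(k=config.knn_k).fit(Zt, labels)
        clf_input_transform = None
    elif config.classifier == "knn_mahalanobis":
        # Mahalanobis metric M = LᵀL applied in the pre-transform space
        metric = make_mahalanobis(transform)
        clf = KnnClassifier(k=config.knn_k, metric=metric).fit(Z, labels)
        clf_input_transform = "pre"
    else:  # ebc
        clf = EnergyClassifier(transform=transform,
                               k_targets=lmnn_cfg.k_targets).fit(Z, labels)
        clf_input_transform = "pre"

    model = FoldModel(
        config=config,
        mean_control=f.data,
        mask_threshold=mask.threshold_value,
        grid_centers=grid.centers,
        grid_side=grid.side,
        selected=scores,
        reducer=reducer,
        transform=None if clf_input_transform == "pre" else transform,
        classifier=clf,
    )
    return model


def run(config: PipelineConfig, manifest: str | Path,
        out_dir: str | Path | None = None):
    """Execute the configured pipeline on a cohort manifest and, if
    ``out_dir`` is given, write report.json, roc.csv, predictions.csv and
    the resolved config."""
    from .evaluation import run_pipeline_cv
    from .volume import load_manifest

    cohort = load_manifest(manifest)
    if config.folds > len(cohort):
        raise ValueError(
            f"folds={config.folds} exceeds cohort size {len(cohort)}")
    report = run_pipeline_cv(cohort, config, seed=config.seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        with open(out_dir / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        np.savetxt(out_dir / "roc.csv", report.roc_points, delimiter=",",
                   header="fpr,tpr", comments="")
        import pandas as pd
        pd.DataFrame({
            "subject_id": [r.subject_id for r in cohort],
            "true": report.true_labels,
            "predicted": report.predicted_labels,
            "score": report.scores,
        }).to_csv(out_dir / "predictions.csv", index=False)
    return report
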