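"""NMSE block features and t-test feature ranking.

The masked brain volume is tiled into non-overlapping cubic blocks (default
5×5×5 voxels).  For each subject p and block centered at (x, y, z) the
normalized mean square error

    NMSE_p(x,y,z) = sum_block (f - g_p)^2 / sum_block f^2

compares the subject's intensities g_p with the mean control image f: it is
0 where the subject matches the control average and grows with regional
hypoperfusion/hypometabolism.  Blocks are then ranked by the absolute value
of a pooled-variance two-sample t statistic between the AD and CTRL rows,
and the top blocks become the feature vector.  The t-test is a ranking
filter here, not an inference, so no multiple-testing correction applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .volume import ActivationMask, BrainVolume, SubjectRecord, POSITIVE_LABEL

__all__ = [
    "BlockGrid",
    "FeatureMatrix",
    "BlockScore",
    "build_block_grid",
    "compute_nmse",
    "nmse_feature_matrix",
    "ttest_rank",
    "select_features",
]


@dataclass
class BlockGrid:
    """Non-overlapping cubic blocks whose centers lie inside the mask."""

    centers: np.ndarray  # (n_blocks, 3) voxel coordinates
    side: int

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.intp).reshape(-1, 3)

    @property
    def half_width(self) -> int:
        return (self.side - 1) // 2

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class FeatureMatrix:
    """Subjects × features table with aligned labels.

    ``column_meaning`` distinguishes raw NMSE block features (ids are block
    centers) from reduced component coordinates (ids are component indices).
    """

    values: np.ndarray
    feature_ids: list
    labels: np.ndarray
    column_meaning: str = "nmse_block"
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (subjects × features)")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("labels not aligned to rows")
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids not aligned to columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            "_".join(str(c) for c in fid) if isinstance(fid, (tuple, np.ndarray)) else str(fid)
            for fid in self.feature_ids
        ]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "label", self.labels)
        if self.subject_ids is not None:
            df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass(frozen=True)
class BlockScore:
    """A block center and its absolute pooled-variance t statistic."""

    center: tuple[int, int, int]
    t_abs: float


def build_block_grid(mask: ActivationMask, side: int = 5) -> BlockGrid:
    """Regular stride-of-``side`` lattice of block centers kept when the
    center voxel is mask-true and the full cube lies in-bounds."""
    if side % 2 == 0 or side < 3:
        raise ValueError(f"block side must be odd and >= 3, got {side}")
    if not mask.mask.any():
        raise ValueError("activation mask is empty")
    hw = (side - 1) // 2
    shape = mask.mask.shape
    axes = [np.arange(hw, dim - hw, side) for dim in shape]
    if any(len(a) == 0 for a in axes):
        raise ValueError(f"volume of shape {shape} too small for side-{side} blocks")
    cx, cy, cz = np.meshgrid(*axes, indexing="ij")
    lattice = np.stack([cx.ravel(), cy.ravel(), cz.ravel()], axis=1)
    keep = mask.mask[lattice[:, 0], lattice[:, 1], lattice[:, 2]]
    return BlockGrid(centers=lattice[keep], side=side)


def _block_slices(center: Sequence[int], half_width: int,
                  shape: Sequence[int]) -> tuple[slice, slice, slice]:
    sl = []
    for c, dim in zip(center, shape):
        lo, hi = int(c) - half_width, int(c) + half_width + 1
        if lo < 0 or hi > dim:
            raise ValueError(f"block at {tuple(center)} exceeds volume bounds {tuple(shape)}")
        sl.append(slice(lo, hi))
    return tuple(sl)  # type: ignore[return-value]


def compute_nmse(f: BrainVolume, g: BrainVolume, center: Sequence[int],
                 half_width: int) -> float:
    """NMSE of subject volume g against the mean-control volume f over one
    cubic block of side ``2·half_width + 1`` centered at ``center``."""
    if f.shape != g.shape:
        raise ValueError("f and g must share one grid")
    sl = _block_slices(center, half_width, f.shape)
    fb = f.data[sl]
    gb = g.data[sl]
    denom = float(np.sum(fb * fb))
    if denom <= 0:
        raise ValueError(f"degenerate block at {tuple(center)}: sum f^2 is zero")
    return float(np.sum((fb - gb) ** 2) / denom)


def nmse_feature_matrix(cohort: Sequence[SubjectRecord], f: BrainVolume,
                        grid: BlockGrid) -> FeatureMatrix:
    """One row per subject, one column per non-degenerate block, column
    order following the grid; degenerate blocks (zero control energy) are
    dropped for the whole cohort."""
    if len(grid) == 0:
        raise ValueError("empty block grid")
    shape = f.shape
    hw = grid.half_width
    side = grid.side
    # flat gather indices, one row of side^3 voxel indices per block
    offs = np.arange(-hw, hw + 1)
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    cube = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)  # (side^3, 3)
    vox = grid.centers[:, None, :] + cube[None, :, :]  # (B, side^3, 3)
    if vox.min() < 0 or np.any(vox.max(axis=(0, 1)) >= np.asarray(shape)):
        raise ValueError("block grid exceeds volume bounds")
    flat_idx = np.ravel_multi_index(
        (vox[..., 0], vox[..., 1], vox[..., 2]), shape)  # (B, side^3)

    f_flat = np.asarray(f.data, dtype=np.float64).ravel()
    denom = (f_flat[flat_idx] ** 2).sum(axis=1)  # (B,)
    keep = denom > 0
    if not keep.any():
        raise ValueError("all blocks degenerate (zero control energy)")
    flat_idx = flat_idx[keep]
    denom = denom[keep]

    rows = np.empty((len(cohort), flat_idx.shape[0]), dtype=np.float64)
    for i, rec in enumerate(cohort):
        if rec.volume.shape != shape:
            raise ValueError(f"subject {rec.subject_id} shape mismatch")
        g_flat = np.asarray(rec.volume.data, dtype=np.float64).ravel()
        resid = f_flat[flat_idx] - g_flat[flat_idx]
        rows[i] = (resid ** 2).sum(axis=1) / denom

    centers = [tuple(int(c) for c in ctr) for ctr in grid.centers[keep]]
    labels = np.array([rec.label for rec in cohort], dtype=int)
    return FeatureMatrix(values=rows, feature_ids=centers, labels=labels,
                         column_meaning="nmse_block",
                         subject_ids=[rec.subject_id for rec in cohort],
                         )


def _pooled_t(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Absolute two-sample t statistic with pooled variance, per column.

    Zero pooled variance with equal means gives |t| = 0; with unequal means
    the statistic is infinite (the feature separates the classes exactly)
    and the column ranks first.
    """
    pos = values[labels == POSITIVE_LABEL]
    neg = values[labels != POSITIVE_LABEL]
    n_pos, n_neg = pos.shape[0], neg.shape[0]
    if n_pos < 2 or n_neg < 2:
        raise ValueError("both classes need at least 2 members for the t-test")
    mean_diff = pos.mean(axis=0) - neg.mean(axis=0)
    sp2 = ((n_pos - 1) * pos.var(axis=0, ddof=1)
           + (n_neg - 1) * neg.var(axis=0, ddof=1)) / (n_pos + n_neg - 2)
    se = np.sqrt(sp2 * (1.0 / n_pos + 1.0 / n_neg))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(mean_diff) / se
    t[(se == 0) & (mean_diff == 0)] = 0.0
    t[(se == 0) & (mean_diff != 0)] = np.inf
    return t


def ttest_rank(features: FeatureMatrix, n_select: int = 200) -> list[BlockScore]:
    """Top ``n_select`` features by |t| descending, ties broken by feature
    index (stable sort)."""
    if n_select > features.n_features:
        raise ValueError(
            f"n_select={n_select} exceeds feature count {features.n_features}")
    t_abs = _pooled_t(features.values, features.labels)
    order = np.argsort(-t_abs, kind="stable")[:n_select]
    return [BlockScore(center=features.feature_ids[i], t_abs=float(t_abs[i]))
            for i in order]


def select_features(features: FeatureMatrix, scores: Sequence[BlockScore]) -> FeatureMatrix:
    """Restrict a FeatureMatrix to the scored features, in score order."""
    index = {fid: j for j, fid in enumerate(features.feature_ids)}
    cols = [index[s.center] for s in scores]
    return FeatureMatrix(values=features.values[:, cols],
                         feature_ids=[features.feature_ids[j] for j in cols],
                         labels=features.labels,
                         column_meaning=features.column_meaning,
                         subject_ids=features.subject_ids)
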