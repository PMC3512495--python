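"""Volume I/O, intensity normalization and activation masking.

Spatially normalized SPECT/PET volumes from different subjects are only
comparable after two steps performed here: (i) per-subject intensity
normalization against a robust maximum (the mean of the brightest voxels),
and (ii) restriction of all downstream analysis to an *activation mask* —
the voxels whose mean-control intensity exceeds half the maximum of the
control average.  Spatial normalization/registration itself is assumed to
have been done upstream; volumes in a cohort must share one grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BrainVolume",
    "SubjectRecord",
    "ActivationMask",
    "read_volume",
    "write_volume",
    "write_mask",
    "normalize_intensity_spect",
    "normalize_intensity_pet",
    "mean_control_volume",
    "compute_activation_mask",
    "load_manifest",
    "save_manifest",
]

#: label conventions: AD (any severity) is the positive class, CTRL negative
POSITIVE_LABEL = 1
NEGATIVE_LABEL = 0
SEVERITY_LEVELS = ("CTRL", "AD1", "AD2", "AD3")


@dataclass
class BrainVolume:
    """A 3D scalar intensity grid with voxel spacing metadata."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3D volume, got {self.data.ndim}D data of shape "
                f"{self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy_with(self, data: np.ndarray) -> "BrainVolume":
        return BrainVolume(data=data, voxel_size_mm=self.voxel_size_mm)


@dataclass
class SubjectRecord:
    """One subject: id, binary label (CTRL=0 / AD=1), volume, optional severity."""

    subject_id: str
    label: int
    volume: BrainVolume
    severity: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (NEGATIVE_LABEL, POSITIVE_LABEL):
            raise ValueError(f"label must be 0 (CTRL) or 1 (AD), got {self.label}")
        if self.severity is not None:
            if self.severity not in SEVERITY_LEVELS:
                raise ValueError(f"unknown severity {self.severity!r}")
            expect = NEGATIVE_LABEL if self.severity == "CTRL" else POSITIVE_LABEL
            if self.label != expect:
                raise ValueError(
                    f"label {self.label} inconsistent with severity {self.severity}"
                )


@dataclass
class ActivationMask:
    """Boolean grid of activated voxels: mean-control intensity > threshold."""

    mask: np.ndarray
    threshold_value: float
    source_shape: tuple[int, int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.source_shape is None:
            self.source_shape = self.mask.shape  # type: ignore[assignment]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def read_volume(path: str | Path) -> BrainVolume:
    """Read a 3D NIfTI volume; raises on missing files and non-3D data."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D data in {path}")
    zooms = img.header.get_zooms()[:3]
    return BrainVolume(data=np.asarray(data, dtype=np.float64),
                       voxel_size_mm=tuple(float(z) for z in zooms))


def write_volume(v: BrainVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with a diagonal voxel-size affine."""
    affine = np.diag(list(v.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(v.data, dtype=np.float64), affine), str(path))


def write_mask(m: ActivationMask, path: str | Path,
               voxel_size_mm: Sequence[float] = (2.0, 2.0, 2.0)) -> None:
    """Persist an activation mask as a uint8 0/1 NIfTI volume."""
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(m.mask.astype(np.uint8), affine), str(path))


def _top_k_count(n_voxels: int, fraction: float) -> int:
    # fraction of the total voxel count, rounded up, never below one voxel
    return max(1, math.ceil(fraction * n_voxels))


def normalize_intensity_spect(v: BrainVolume, top_fraction: float = 0.03) -> BrainVolume:
    """Divide by the mean of the brightest ``top_fraction`` of all voxels.

    The reference level I_max is the average over the highest-ranked 3 % of
    voxel intensities, so the output is dimensionless with the brightest
    tissue at level 1.  Idempotent: renormalizing a normalized volume is the
    identity.
    """
    flat = np.asarray(v.data, dtype=np.float64).ravel()
    k = _top_k_count(flat.size, top_fraction)
    top = np.partition(flat, flat.size - k)[flat.size - k:]
    imax = float(top.mean())
    if imax <= 0:
        raise ValueError("cannot normalize: no positive reference intensity")
    return v.copy_with(v.data / imax)


def normalize_intensity_pet(v: BrainVolume, top_fraction: float = 0.001,
                            n_bins: int = 50, threshold_bin: int = 10) -> BrainVolume:
    """PET intensity normalization with histogram-based background rejection.

    A ``n_bins``-bin equal-width histogram spans [min, max] of the volume;
    voxels below the lower edge of ``threshold_bin`` (1-based) are discarded
    as out-of-brain background, and I_max is the mean of the brightest
    ``top_fraction`` of the surviving voxels.
    """
    flat = np.asarray(v.data, dtype=np.float64).ravel()
    lo, hi = float(flat.min()), float(flat.max())
    if hi <= lo:
        raise ValueError("cannot normalize: volume has zero dynamic range")
    threshold = lo + (threshold_bin - 1) * (hi - lo) / n_bins
    surviving = flat[flat >= threshold]
    if surviving.size < 1:
        raise ValueError("no voxels survive the histogram threshold")
    k = _top_k_count(surviving.size, top_fraction)
    top = np.partition(surviving, surviving.size - k)[surviving.size - k:]
    imax = float(top.mean())
    if imax <= 0:
        raise ValueError("cannot normalize: non-positive reference intensity")
    return v.copy_with(v.data / imax)


def mean_control_volume(cohort: Sequence[SubjectRecord]) -> BrainVolume:
    """Voxelwise arithmetic mean over the control-labeled subjects only."""
    controls = [s for s in cohort if s.label == NEGATIVE_LABEL]
    if not controls:
        raise ValueError("cohort contains no control subjects")
    shape = controls[0].volume.shape
    for s in controls:
        if s.volume.shape != shape:
            raise ValueError(
                f"shape mismatch: {s.subject_id} has {s.volume.shape}, expected {shape}"
            )
    acc = np.zeros(shape, dtype=np.float64)
    for s in controls:
        acc += s.volume.data
    return controls[0].volume.copy_with(acc / len(controls))


def compute_activation_mask(mean_vol: BrainVolume, fraction: float = 0.5) -> ActivationMask:
    """Mask of voxels whose mean-control intensity strictly exceeds
    ``fraction`` times the maximum of the mean image."""
    vmax = float(mean_vol.data.max())
    if vmax <= 0:
        raise ValueError("mean volume has non-positive maximum; cannot threshold")
    threshold = fraction * vmax
    return ActivationMask(mask=mean_vol.data > threshold, threshold_value=threshold,
                          source_shape=mean_vol.shape)


def load_manifest(path: str | Path, read_volumes: bool = True) -> list[SubjectRecord]:
    """Load a cohort manifest CSV (columns subject_id,label,severity,path)."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "label", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        severity = getattr(row, "severity", None)
        if isinstance(severity, float) and np.isnan(severity):
            severity = None
        vol_path = Path(row.path)
        if not vol_path.is_absolute():
            vol_path = path.parent / vol_path
        volume = read_volume(vol_path) if read_volumes else BrainVolume(np.zeros((1, 1, 1)))
        records.append(SubjectRecord(subject_id=str(row.subject_id),
                                     label=int(row.label), volume=volume,
                                     severity=severity))
    return records


def save_manifest(records: Sequence[SubjectRecord], paths: Sequence[str | Path],
                  out: str | Path) -> None:
    rows = [
        {"subject_id": r.subject_id, "label": r.label,
         "severity": r.severity if r.severity is not None else "",
         "path": str(p)}
        for r, p in zip(records, paths)
    ]
    pd.DataFrame(rows).to_csv(out, index=False)
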