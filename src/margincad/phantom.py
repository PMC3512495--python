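"""Synthetic hypoperfusion phantoms: labeled 3D brain-like cohorts.

Each subject is an ellipsoidal "brain" of uniform baseline intensity on a
zero background, scaled by a per-subject multiplicative gain (lognormal —
global tracer-uptake/dose variation that the per-subject intensity
normalization must remove), with spatially smooth additive Gaussian noise.
AD-class subjects additionally carry *multiplicative* intensity deficits in
configurable ellipsoidal regions: perfusion and metabolism scale with
intensity, so a severity factor of 0.75 means the region retains 75 % of
the control-level signal.  Severity classes AD1/AD2/AD3 (mild → severe) map
to progressively deeper deficit factors.

The noise field (not the signal) is Gaussian-blurred, which emulates
scanner-resolution-correlated noise while keeping the ground-truth region
edges crisp for overlap scoring.  Cohorts are bit-reproducible from
(PhantomSpec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import BrainVolume, SubjectRecord, save_manifest, write_volume

__all__ = [
    "DeficitRegion",
    "PhantomSpec",
    "TruthTable",
    "generate_cohort",
    "default_ad_spec",
    "write_cohort",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _ellipsoid_mask(shape: Sequence[int], center: Sequence[float],
                    semi_axes: Sequence[float]) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


@dataclass(frozen=True)
class DeficitRegion:
    """An ellipsoidal hypoperfusion region with per-severity-class factors."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    severity_factors: dict[str, float]  # e.g. {"AD1": 0.85, "AD2": 0.75, "AD3": 0.6}

    def __post_init__(self) -> None:
        for cls, f in self.severity_factors.items():
            if not 0.0 < f <= 1.0:
                raise ValueError(f"severity factor for {cls} must be in (0, 1]")


@dataclass
class PhantomSpec:
    """Geometry and noise model of a phantom cohort."""

    shape: tuple[int, int, int] = (95, 69, 79)
    brain_center: tuple[float, float, float] = (47.0, 34.0, 39.0)
    brain_semi_axes: tuple[float, float, float] = (40.0, 29.0, 33.0)
    deficit_regions: list[DeficitRegion] = field(default_factory=list)
    baseline_intensity: float = 100.0
    noise_sigma: float = 10.0
    smoothing_fwhm_vox: float = 2.0
    subject_gain_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.subject_gain_sigma < 0:
            raise ValueError("subject_gain_sigma must be >= 0")
        brain = self.brain_mask()
        for i, region in enumerate(self.deficit_regions):
            rmask = _ellipsoid_mask(self.shape, region.center, region.semi_axes)
            if np.any(rmask & ~brain):
                raise ValueError(f"deficit region {i} extends outside the brain")

    def brain_mask(self) -> np.ndarray:
        return _ellipsoid_mask(self.shape, self.brain_center, self.brain_semi_axes)

    def region_masks(self) -> list[np.ndarray]:
        return [_ellipsoid_mask(self.shape, r.center, r.semi_axes)
                for r in self.deficit_regions]


@dataclass
class TruthTable:
    """Ground truth of a generated cohort, for recovery scoring."""

    region_masks: list[np.ndarray]
    subject_severity: dict[str, str]
    subject_gain: dict[str, float]
    master_seed: int

    def region_voxels(self) -> np.ndarray:
        """Union of all planted deficit regions (boolean grid)."""
        if not self.region_masks:
            raise ValueError("no deficit regions planted")
        out = np.zeros_like(self.region_masks[0], dtype=bool)
        for m in self.region_masks:
            out |= m
        return out


def default_ad_spec(severity_factors: dict[str, float] | None = None) -> PhantomSpec:
    """Phantom emulating the qualitative AD hypoperfusion topography:
    bilateral temporo-parietal regions plus a posterior midline
    (cingulate/precuneus-like) region, on the 95×69×79 grid of 2 mm voxels.

    Deficit factors default to 0.85 / 0.75 / 0.60 for mild / moderate /
    severe disease (AD1/AD2/AD3).
    """
    if severity_factors is None:
        severity_factors = {"AD1": 0.85, "AD2": 0.75, "AD3": 0.60}
    regions = [
        DeficitRegion(center=(24.0, 34.0, 34.0), semi_axes=(8.0, 10.0, 9.0),
                      severity_factors=dict(severity_factors)),
        DeficitRegion(center=(70.0, 34.0, 34.0), semi_axes=(8.0, 10.0, 9.0),
                      severity_factors=dict(severity_factors)),
        DeficitRegion(center=(47.0, 20.0, 46.0), semi_axes=(7.0, 8.0, 8.0),
                      severity_factors=dict(severity_factors)),
    ]
    return PhantomSpec(deficit_regions=regions)


#: default AD1/AD2/AD3 proportions, mirroring a mild-heavy clinical mix
DEFAULT_SEVERITY_MIX = {"AD1": 30 / 56, "AD2": 22 / 56, "AD3": 4 / 56}


def generate_cohort(spec: PhantomSpec, n_ctrl: int, n_ad: int,
                    severity_mix: dict[str, float] | None = None,
                    seed: int | None = None
                    ) -> tuple[list[SubjectRecord], TruthTable]:
    """Generate ``n_ctrl`` control and ``n_ad`` AD subjects.

    AD severities are assigned deterministically in proportion to
    ``severity_mix`` (largest remainder), then shuffled with the cohort RNG.
    ``seed`` overrides ``spec.seed``.
    """
    if n_ctrl < 1 or n_ad < 1:
        raise ValueError("need at least one subject per class")
    if severity_mix is None:
        severity_mix = dict(DEFAULT_SEVERITY_MIX)
    total = sum(severity_mix.values())
    if total <= 0 or any(v < 0 for v in severity_mix.values()):
        raise ValueError("invalid severity proportions")
    mix = {k: v / total for k, v in severity_mix.items()}

    master_seed = spec.seed if seed is None else seed
    root = np.random.SeedSequence(master_seed)
    cohort_rng = np.random.default_rng(root.spawn(1)[0])

    # largest-remainder apportionment of severities over the AD subjects
    classes = sorted(mix)
    raw = {c: mix[c] * n_ad for c in classes}
    counts = {c: int(np.floor(raw[c])) for c in classes}
    short = n_ad - sum(counts.values())
    for c in sorted(classes, key=lambda c: (-(raw[c] - counts[c]), c))[:short]:
        counts[c] += 1
    severities = [c for c in classes for _ in range(counts[c])]
    cohort_rng.shuffle(severities)

    brain = spec.brain_mask()
    region_masks = spec.region_masks()
    base = spec.baseline_intensity * brain.astype(np.float32)
    noise_blur = spec.smoothing_fwhm_vox * _FWHM_TO_SIGMA

    subject_streams = root.spawn(n_ctrl + n_ad)
    records: list[SubjectRecord] = []
    truth_sev: dict[str, str] = {}
    truth_gain: dict[str, float] = {}

    def build(subject_id: str, severity: str, stream) -> SubjectRecord:
        rng = np.random.default_rng(stream)
        gain = float(rng.lognormal(mean=0.0, sigma=spec.subject_gain_sigma)) \
            if spec.subject_gain_sigma > 0 else 1.0
        vol = base * gain
        if severity != "CTRL":
            for region, rmask in zip(spec.deficit_regions, region_masks):
                factor = region.severity_factors.get(severity)
                if factor is None:
                    raise ValueError(f"region lacks a factor for {severity}")
                vol = np.where(rmask, vol * factor, vol)
        if spec.noise_sigma > 0:
            noise = rng.normal(0.0, spec.noise_sigma, size=spec.shape)
            if noise_blur > 0:
                noise = gaussian_filter(noise, sigma=noise_blur)
            vol = vol + noise
        vol = np.clip(vol, 0.0, None).astype(np.float32)
        truth_sev[subject_id] = severity
        truth_gain[subject_id] = gain
        label = 0 if severity == "CTRL" else 1
        return SubjectRecord(subject_id=subject_id, label=label,
                             volume=BrainVolume(vol), severity=severity)

    for i in range(n_ctrl):
        records.append(build(f"CTRL{i + 1:03d}", "CTRL", subject_streams[i]))
    for i in range(n_ad):
        records.append(build(f"AD{i + 1:03d}", severities[i],
                             subject_streams[n_ctrl + i]))

    truth = TruthTable(region_masks=region_masks, subject_severity=truth_sev,
                       subject_gain=truth_gain, master_seed=master_seed)
    return records, truth


def write_cohort(records: Sequence[SubjectRecord], truth: TruthTable,
                 out_dir: str | Path) -> Path:
    """Write NIfTI volumes, a manifest CSV and truth.json to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in records:
        p = f"{rec.subject_id}.nii.gz"
        write_volume(rec.volume, out_dir / p)
        paths.append(p)
    save_manifest(records, paths, out_dir / "manifest.csv")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump({
            "master_seed": truth.master_seed,
            "subject_severity": truth.subject_severity,
            "subject_gain": truth.subject_gain,
            "n_regions": len(truth.region_masks),
            "region_voxel_counts": [int(m.sum()) for m in truth.region_masks],
        }, fh, indent=2)
    return out_dir
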