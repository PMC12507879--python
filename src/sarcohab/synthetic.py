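"""Synthetic cohorts of paraspinal-muscle ROIs with known muscle/fat truth.

Each subject is an ellipsoidal region of interest whose voxels are drawn
from a two-component Gaussian intensity mixture — muscle and fat — with the
fat weight drawn per subject from a group-specific distribution.  A small
fraction of interface voxels mixes the two tissue intensities
(partial-volume effect), as at real muscle/fat boundaries; their
ground-truth label is the majority tissue.  Sarcopenia raises the expected
fat fraction (fatty infiltration) and shrinks the ROI (muscle atrophy).  Polarity follows the contrast physics of each modality:
on CT fat is hypodense relative to muscle (negative Hounsfield units),
while on non-fat-suppressed T2-weighted MRI fat is hyperintense.

Per-subject scanner effects are emulated by an additive intensity offset
(both modalities) and, for MRI, a multiplicative gain, reflecting the
arbitrary intensity scale of unnormalised T2-weighted images acquired on
different scanners.  Clinical covariates are drawn from group-specific
normals.

Randomness is organised so that the anatomy (ROI mask, per-voxel tissue
labels, covariates) of a subject depends only on the master seed, the group
sizes and the fat-fraction parameters — not on the modality or intensity
settings.  Generating a CT cohort and an MRI cohort from the same seed
therefore yields *paired* subjects imaged in both modalities, as in a
cohort where every patient receives both scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .volumes import IntensityVolume, RoiMask, save_mask, save_volume

#: Muscle/fat intensity models per modality.  CT is on the Hounsfield scale
#: (fat ~ -90 HU, muscle ~ +50 HU); MRI is an arbitrary T2WI scale with fat
#: bright.  MRI jitter is much larger than CT jitter: HU are calibrated,
#: T2WI intensities are not, and cross-scanner gain differences dominate.
MODALITY_INTENSITY_DEFAULTS: dict[str, dict[str, float]] = {
    "CT": {
        "muscle_mean": 50.0,
        "fat_mean": -90.0,
        "component_sd": 15.0,
        "intensity_jitter_sd": 5.0,
        "gain_jitter_sd": 0.0,
        "background": -1000.0,
    },
    "MRI": {
        "muscle_mean": 300.0,
        "fat_mean": 900.0,
        "component_sd": 120.0,
        "intensity_jitter_sd": 150.0,
        "gain_jitter_sd": 0.35,
        "background": 0.0,
    },
}

#: Group-specific clinical covariate distributions (mean, sd), indexed by
#: sarcopenia status.  Values follow published demographic profiles of
#: elderly surgical cohorts: sarcopenic patients are older, leaner and
#: hypo-albuminaemic, with mildly lower haemoglobin and red-cell counts.
COVARIATE_DEFAULTS: dict[str, dict[int, tuple[float, float]]] = {
    "age": {0: (68.13, 6.88), 1: (71.65, 7.01)},
    "bmi": {0: (24.99, 3.40), 1: (22.83, 3.18)},
    "albumin": {0: (37.89, 3.09), 1: (35.90, 3.32)},
    "hemoglobin": {0: (136.76, 18.03), 1: (130.77, 16.31)},
    "rbc": {0: (4.50, 0.54), 1: (4.36, 0.48)},
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Intensity parameters left as ``None`` resolve to the modality defaults
    in :data:`MODALITY_INTENSITY_DEFAULTS`.
    """

    modality: str = "CT"
    n_non_sarcopenia: int = 100
    n_sarcopenia: int = 100
    roi_shape: tuple[int, int, int] = (24, 24, 12)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fat_fraction_mean_by_group: tuple[float, float] = (0.15, 0.45)
    fat_fraction_sd: float = 0.08
    partial_volume_fraction: float = 0.05  # interface voxels mixing tissues
    sarcopenia_roi_scale: float = 0.85  # linear shrink of ROI semi-axes
    muscle_mean: float | None = None
    fat_mean: float | None = None
    component_sd: float | None = None
    intensity_jitter_sd: float | None = None
    gain_jitter_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.modality not in MODALITY_INTENSITY_DEFAULTS:
            raise ConfigurationError(f"unknown modality {self.modality!r}")
        if self.n_non_sarcopenia < 1 or self.n_sarcopenia < 1:
            raise ConfigurationError("both groups need at least one subject")
        if len(self.roi_shape) != 3 or any(int(n) < 1 for n in self.roi_shape):
            raise ConfigurationError("roi_shape must be 3 positive ints")
        f0, f1 = self.fat_fraction_mean_by_group
        for f in (f0, f1):
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError(
                    f"fat fraction mean {f} outside the unit interval")
        if f1 < f0:
            raise ConfigurationError(
                "sarcopenia fat-fraction mean must be >= non-sarcopenia mean")
        if self.fat_fraction_sd < 0:
            raise ConfigurationError("fat_fraction_sd must be >= 0")
        if not (0.0 <= self.partial_volume_fraction < 1.0):
            raise ConfigurationError(
                "partial_volume_fraction must be in [0, 1)")
        if not (0 < self.sarcopenia_roi_scale <= 1):
            raise ConfigurationError("sarcopenia_roi_scale must be in (0, 1]")
        fat, muscle = self.resolved("fat_mean"), self.resolved("muscle_mean")
        if self.modality == "CT" and fat >= muscle:
            raise ConfigurationError("CT fat mean must lie below muscle mean")
        if self.modality == "MRI" and fat <= muscle:
            raise ConfigurationError("MRI fat mean must lie above muscle mean")

    def resolved(self, name: str) -> float:
        value = getattr(self, name)
        if value is None:
            value = MODALITY_INTENSITY_DEFAULTS[self.modality][name]
        return float(value)

    @property
    def n_total(self) -> int:
        return self.n_non_sarcopenia + self.n_sarcopenia

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("roi_shape", "spacing", "fat_fraction_mean_by_group"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SubjectRecord:
    """Clinical covariates, group label, and generator ground truth."""

    subject_id: str
    sarcopenia: int
    age: float
    bmi: float
    albumin: float
    hemoglobin: float
    rbc: float
    true_fat_fraction: float

    def __post_init__(self) -> None:
        if self.sarcopenia not in (0, 1):
            raise ConfigurationError("sarcopenia label must be 0 or 1")
        for name in ("age", "bmi", "albumin"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")


@dataclass
class SyntheticSubject:
    """One generated subject: image, ROI, record, and per-voxel truth.

    ``true_labels`` uses the habitat code convention 0 = outside ROI,
    1 = muscle, 2 = fat.
    """

    volume: IntensityVolume
    mask: RoiMask
    record: SubjectRecord
    true_labels: np.ndarray


def _ellipsoid_mask(shape: Sequence[int], scale: float) -> np.ndarray:
    semi = [max(0.5, 0.45 * n * scale) for n in shape]
    centre = [(n - 1) / 2.0 for n in shape]
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    mask = r2 <= 1.0
    if not mask.any():  # degenerate tiny grids: keep the central voxel
        mask[tuple(int(c) for c in centre)] = True
    return mask


def _draw_covariates(rng: np.random.Generator, group: int) -> dict[str, float]:
    out = {}
    for name, by_group in COVARIATE_DEFAULTS.items():
        mean, sd = by_group[group]
        value = rng.normal(mean, sd)
        # covariates are physically positive; redraw the rare negative tail
        while value <= 0:
            value = rng.normal(mean, sd)
        out[name] = float(value)
    return out


def _subject_seedseq(master_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def generate_subject(config: GeneratorConfig, group: int, index: int = 0,
                     subject_id: str | None = None) -> SyntheticSubject:
    """Generate one subject of the given group.

    ``index`` keys the subject's random streams off the master seed so that
    cohort generation is reproducible and order-independent.  Three child
    streams are used — covariates, tissue labels, intensity rendering — so
    anatomy and covariates are shared across modalities at a fixed seed.
    """
    if group not in (0, 1):
        raise ConfigurationError("group must be 0 or 1")
    config.validate()
    ss = _subject_seedseq(config.seed, index)
    cov_ss, label_ss, render_ss = ss.spawn(3)
    cov_rng = np.random.default_rng(cov_ss)
    label_rng = np.random.default_rng(label_ss)
    render_rng = np.random.default_rng(render_ss)

    scale = config.sarcopenia_roi_scale if group == 1 else 1.0
    roi = _ellipsoid_mask(config.roi_shape, scale)
    n_vox = int(roi.sum())

    f_target = config.fat_fraction_mean_by_group[group]
    if config.fat_fraction_sd > 0:
        f_target = float(np.clip(
            label_rng.normal(f_target, config.fat_fraction_sd), 0.0, 1.0))
    is_fat = label_rng.random(n_vox) < f_target

    mu_m = config.resolved("muscle_mean")
    mu_f = config.resolved("fat_mean")
    sd = config.resolved("component_sd")
    gain_sd = config.resolved("gain_jitter_sd")
    offset_sd = config.resolved("intensity_jitter_sd")
    gain = 1.0
    if gain_sd > 0:
        gain = float(np.clip(render_rng.normal(1.0, gain_sd), 0.2, None))
    offset = float(render_rng.normal(0.0, offset_sd)) if offset_sd > 0 else 0.0

    means = np.where(is_fat, mu_f, mu_m).astype(np.float64)
    # muscle/fat interface voxels average the two tissues (partial-volume
    # effect); the ground-truth label stays the majority tissue, so the
    # mixing weight of the labelled tissue is uniform on (0.5, 1)
    if config.partial_volume_fraction > 0:
        pv = label_rng.random(n_vox) < config.partial_volume_fraction
        alpha = 0.5 + 0.5 * label_rng.random(n_vox)  # majority-tissue weight
        other = np.where(is_fat, mu_m, mu_f)
        means[pv] = (alpha[pv] * means[pv] + (1.0 - alpha[pv]) * other[pv])
    roi_values = gain * render_rng.normal(means, sd) + offset
    if config.modality == "MRI":
        # magnitude MR images are non-negative; strong negative offsets
        # floor at zero rather than producing unphysical intensities
        roi_values = np.maximum(roi_values, 0.0)

    background = MODALITY_INTENSITY_DEFAULTS[config.modality]["background"]
    voxels = np.full(config.roi_shape, background, dtype=np.float64)
    voxels[roi] = roi_values
    labels = np.zeros(config.roi_shape, dtype=np.int8)
    labels[roi] = np.where(is_fat, 2, 1)

    covs = _draw_covariates(cov_rng, group)
    record = SubjectRecord(
        subject_id=subject_id or f"S{index:04d}",
        sarcopenia=group,
        true_fat_fraction=float(is_fat.mean()),
        **covs,
    )
    return SyntheticSubject(
        volume=IntensityVolume(voxels, config.spacing, config.modality),
        mask=RoiMask(roi, config.spacing),
        record=record,
        true_labels=labels,
    )


def generate_cohort(config: GeneratorConfig) -> list[SyntheticSubject]:
    """Generate the full cohort: non-sarcopenia subjects first, then
    sarcopenia, with per-subject seeds split off the master seed."""
    config.validate()
    groups = [0] * config.n_non_sarcopenia + [1] * config.n_sarcopenia
    return [generate_subject(config, group, index=i)
            for i, group in enumerate(groups)]


def records_frame(cohort: Sequence[SyntheticSubject]) -> pd.DataFrame:
    """Subject metadata table, one row per subject."""
    return pd.DataFrame([asdict(s.record) for s in cohort])


def write_cohort(cohort: Sequence[SyntheticSubject], out_dir: str | Path,
                 config: GeneratorConfig | None = None) -> Path:
    """Write a cohort to disk: NIfTI volume+mask per subject, CSV metadata.

    Layout: ``<out>/volumes/<id>_<modality>.nii.gz``,
    ``<out>/masks/<id>.nii.gz``, ``<out>/subjects.csv``, and the generator
    configuration as ``<out>/generator.yaml`` when given.
    """
    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for subject in cohort:
        sid = subject.record.subject_id
        save_volume(subject.volume,
                    out / "volumes" / f"{sid}_{subject.volume.modality}.nii.gz")
        save_mask(subject.mask, out / "masks" / f"{sid}.nii.gz")
    cols = ["subject_id", "sarcopenia", "age", "bmi", "albumin",
            "hemoglobin", "rbc"]
    records_frame(cohort)[cols].to_csv(out / "subjects.csv", index=False)
    if config is not None:
        config.to_yaml(out / "generator.yaml")
    return out
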