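"""Per-subject habitat quantification: mean intensity, volume, percentage.

A *habitat* is the sub-region of the ROI assigned to one tissue class
(muscle or fat) by thresholding.  For each subject six candidate
predictors are computed: fat mean / volume / percentage and muscle
mean / volume / percentage.  Percentages are stored as fractions in
[0, 1]; volumes are in mm^3 (voxel count times voxel volume, 1 mm^3 after
isotropic resampling).  The mean of an empty habitat is *missing* (NaN),
never 0 — zero is a perfectly valid intensity on both scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import LABEL_FAT, LABEL_MUSCLE
from .errors import EmptyRoiError, InputError
from .volumes import IntensityVolume, RoiMask

#: Canonical habitat feature column order (without the modality prefix).
FEATURE_SUFFIXES = ("fat_Mean", "fat_Volume", "fat_Percent",
                    "muscle_Mean", "muscle_Volume", "muscle_Percent")


@dataclass
class HabitatFeatures:
    subject_id: str
    fat_mean: float       # NaN when the fat habitat is empty
    fat_volume: float     # mm^3
    fat_percent: float    # fraction of ROI voxels
    muscle_mean: float
    muscle_volume: float
    muscle_percent: float


def compute_features(volume: IntensityVolume, mask: RoiMask,
                     labels: np.ndarray,
                     subject_id: str = "") -> HabitatFeatures:
    """Summarise one subject's muscle/fat habitats.

    ``labels`` is the integer label grid from
    :func:`~sarcohab.clustering.classify_voxels`; it must cover exactly the
    mask foreground with muscle/fat codes.
    """
    labels = np.asarray(labels)
    if labels.shape != mask.shape or volume.shape != mask.shape:
        raise InputError("volume, mask and label grid shapes must match")
    roi = mask.voxels
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise EmptyRoiError("empty ROI")
    roi_labels = labels[roi]
    if not np.all((roi_labels == LABEL_FAT) | (roi_labels == LABEL_MUSCLE)):
        raise InputError("ROI voxels must all be labelled muscle or fat")
    voxel_vol = volume.voxel_volume_mm3
    values = volume.voxels[roi]

    out: dict[str, float] = {}
    for name, code in (("fat", LABEL_FAT), ("muscle", LABEL_MUSCLE)):
        sel = roi_labels == code
        n = int(sel.sum())
        out[f"{name}_mean"] = float(values[sel].mean()) if n else math.nan
        out[f"{name}_volume"] = n * voxel_vol
        out[f"{name}_percent"] = n / n_roi
    return HabitatFeatures(subject_id=subject_id, **out)


def feature_table(features: Sequence[HabitatFeatures],
                  records: pd.DataFrame | None = None,
                  modality: str = "CT") -> pd.DataFrame:
    """One row per subject; habitat columns named ``<MOD>_<habitat>_<stat>``
    (e.g. ``CT_fat_Mean``), optionally joined with subject covariates.

    ``records`` must carry a ``subject_id`` column when given.
    """
    if len(features) == 0:
        raise InputError("need at least one subject")
    ids = [f.subject_id for f in features]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate subject_id in feature list")
    rows = []
    for f in features:
        d = asdict(f)
        row = {"subject_id": d.pop("subject_id")}
        for suffix in FEATURE_SUFFIXES:
            habitat, stat = suffix.split("_")
            row[f"{modality}_{suffix}"] = d[f"{habitat}_{stat.lower()}"]
        rows.append(row)
    table = pd.DataFrame(rows)
    if records is not None:
        if "subject_id" not in records.columns:
            raise InputError("records must have a subject_id column")
        if records["subject_id"].duplicated().any():
            raise InputError("duplicate subject_id in records")
        table = records.merge(table, on="subject_id", how="right")
    return table


def feature_columns(modality: str) -> list[str]:
    """The six habitat predictor column names for one modality."""
    return [f"{modality}_{suffix}" for suffix in FEATURE_SUFFIXES]
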