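"""Volume and ROI-mask containers, isotropic resampling, and cohort pooling.

Conventions
-----------
* Voxel grids are 3-D numpy arrays indexed ``[i, j, k]``; axis 0 is the
  slowest-varying axis.  The physical position of voxel ``(i, j, k)`` is
  ``(i * sx, j * sy, k * sz)`` — voxel centres sit on a regular lattice
  anchored at the origin.
* ROI extraction walks the grid in C (raster) order, slowest axis first,
  so pooled intensity vectors are reproducible across runs and platforms.
* Volumes and their masks are assumed co-registered: same shape, same
  spacing.  Orientation metadata beyond the voxel spacing is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import EmptyRoiError, InputError

MODALITIES = ("CT", "MRI")


def _check_modality(modality: str) -> str:
    if modality not in MODALITIES:
        raise InputError(f"modality must be one of {MODALITIES}, got {modality!r}")
    return modality


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise InputError(f"spacing must be 3 positive floats, got {spacing}")
    return spacing


@dataclass
class IntensityVolume:
    """A 3-D scalar image with voxel spacing in mm and a modality tag."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    modality: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise InputError("volume must be a non-empty 3-D grid")
        if not np.all(np.isfinite(self.voxels)):
            raise InputError("volume contains non-finite intensities")
        self.spacing = _check_spacing(self.spacing)
        self.modality = _check_modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class RoiMask:
    """A binary region-of-interest mask aligned with an intensity volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3 or arr.size == 0:
            raise InputError("mask must be a non-empty 3-D grid")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise InputError("mask voxels must be binary (0/1)")
        self.voxels = arr.astype(bool)
        self.spacing = _check_spacing(self.spacing)
        if not self.voxels.any():
            raise EmptyRoiError("mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    @property
    def roi_volume_mm3(self) -> float:
        return self.n_foreground * float(np.prod(self.spacing))


@dataclass
class PooledIntensities:
    """ROI intensities of many subjects concatenated into one global vector.

    ``offsets[s] = (start, stop)`` recovers subject ``s``'s segment as
    ``values[start:stop]``; the segments partition the vector.
    """

    values: np.ndarray
    offsets: list[tuple[int, int]]
    subject_ids: list[str]
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.modality = _check_modality(self.modality)
        if len(self.offsets) != len(self.subject_ids):
            raise InputError("offsets and subject_ids must align")
        pos = 0
        for start, stop in self.offsets:
            if start != pos or stop < start:
                raise InputError("offsets must partition the pooled vector")
            pos = stop
        if pos != self.values.size:
            raise InputError("offsets do not cover the pooled vector")

    def subject_values(self, index: int) -> np.ndarray:
        start, stop = self.offsets[index]
        return self.values[start:stop]


def _output_shape(shape: Sequence[int], spacing: Sequence[float],
                  target: Sequence[float]) -> tuple[int, ...]:
    return tuple(max(1, int(round(n * s / t)))
                 for n, s, t in zip(shape, spacing, target))


def _resample_grid(voxels: np.ndarray, spacing: Sequence[float],
                   target: Sequence[float], order: int) -> np.ndarray:
    out_shape = _output_shape(voxels.shape, spacing, target)
    if out_shape == voxels.shape and tuple(spacing) == tuple(target):
        return voxels.copy()
    axes = [np.arange(n) * t / s for n, s, t in zip(out_shape, spacing, target)]
    coords = np.meshgrid(*axes, indexing="ij")
    # clamp at the boundary so the last partial voxel replicates the edge
    return ndimage.map_coordinates(voxels, coords, order=order, mode="nearest")


def resample_isotropic(volume: IntensityVolume,
                       target_spacing: Sequence[float] = (1.0, 1.0, 1.0)
                       ) -> IntensityVolume:
    """Trilinearly resample a volume onto a new voxel lattice.

    The output grid has ``round(dim * spacing / target)`` voxels per axis
    (at least 1) and its voxel centres at multiples of the target spacing,
    sharing the origin voxel centre with the input.
    """
    target = _check_spacing(target_spacing)
    out = _resample_grid(volume.voxels, volume.spacing, target, order=1)
    return IntensityVolume(out, target, volume.modality)


def resample_mask(mask: RoiMask,
                  target_spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> RoiMask:
    """Nearest-neighbour resample of a binary mask; output stays binary.

    Raises :class:`EmptyRoiError` if no foreground voxel survives.
    """
    target = _check_spacing(target_spacing)
    out = _resample_grid(mask.voxels.astype(np.uint8), mask.spacing, target,
                         order=0)
    return RoiMask(out.astype(bool), target)


def extract_roi_intensities(volume: IntensityVolume, mask: RoiMask) -> np.ndarray:
    """Return ROI voxel intensities as a 1-D vector in raster (C) order."""
    if volume.shape != mask.shape:
        raise InputError(
            f"volume shape {volume.shape} != mask shape {mask.shape}")
    if volume.spacing != mask.spacing:
        raise InputError("volume and mask spacing differ")
    return volume.voxels[mask.voxels]


def pool_cohort(volumes: Sequence[IntensityVolume], masks: Sequence[RoiMask],
                subject_ids: Sequence[str] | None = None) -> PooledIntensities:
    """Concatenate per-subject ROI intensity vectors into a global matrix.

    All volumes must share one modality; pooling across modalities would mix
    incompatible intensity scales.
    """
    if len(volumes) == 0 or len(volumes) != len(masks):
        raise InputError("need >=1 (volume, mask) pair, equal counts")
    modalities = {v.modality for v in volumes}
    if len(modalities) != 1:
        raise InputError(f"mixed modalities in cohort: {sorted(modalities)}")
    if subject_ids is None:
        subject_ids = [f"S{i:04d}" for i in range(len(volumes))]
    segments = [extract_roi_intensities(v, m) for v, m in zip(volumes, masks)]
    offsets: list[tuple[int, int]] = []
    pos = 0
    for seg in segments:
        offsets.append((pos, pos + seg.size))
        pos += seg.size
    return PooledIntensities(np.concatenate(segments), offsets,
                             list(subject_ids), modalities.pop())


# ---------------------------------------------------------------------------
# NIfTI I/O — spacing is carried on the affine diagonal.

def save_volume(volume: IntensityVolume, path: str | Path) -> None:
    affine = np.diag((*volume.spacing, 1.0))
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_volume(path: str | Path, modality: str) -> IntensityVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return IntensityVolume(np.asarray(img.dataobj, dtype=np.float64),
                           spacing, modality)


def save_mask(mask: RoiMask, path: str | Path) -> None:
    affine = np.diag((*mask.spacing, 1.0))
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def load_mask(path: str | Path) -> RoiMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return RoiMask(np.asarray(img.dataobj).astype(bool), spacing)
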