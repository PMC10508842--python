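"""In-memory containers for volumes and lesion masks.

Volumes are plain 3D scalar grids with isotropic-in-plane voxel spacing
metadata; axial slices are ``array[:, :, k]``. NIfTI round-tripping lives
here so the rest of the package never touches nibabel directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Tuple

import nibabel as nib
import numpy as np

Timepoint = str  # "baseline" | "followup"
Sequence = str   # "T2W" | "ADC"

TIMEPOINTS: Tuple[str, str] = ("baseline", "followup")
SEQUENCES: Tuple[str, str] = ("T2W", "ADC")


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing and acquisition metadata."""

    array: np.ndarray                      # float array, shape (nx, ny, nz)
    spacing_mm: Tuple[float, float, float]
    sequence: Sequence = "T2W"
    patient_id: str = ""
    timepoint: Timepoint = "baseline"

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=np.float64)
        if self.array.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.array.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.array.shape  # type: ignore[return-value]

    def with_array(self, array: np.ndarray) -> "ImageVolume":
        return replace(self, array=np.asarray(array, dtype=np.float64))

    def slices(self) -> Iterator[np.ndarray]:
        for k in range(self.array.shape[2]):
            yield self.array[:, :, k]


@dataclass
class RoiMask:
    """Binary lesion mask on an :class:`ImageVolume` grid."""

    array: np.ndarray                      # bool array, shape (nx, ny, nz)
    spacing_mm: Tuple[float, float, float]
    patient_id: str = ""
    timepoint: Timepoint = "baseline"

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array).astype(bool)
        if self.array.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.array.shape}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.array.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.array.sum())

    def volume_cc(self) -> float:
        """Lesion volume in cubic centimetres."""
        voxel_mm3 = float(np.prod(self.spacing_mm))
        return self.n_voxels * voxel_mm3 / 1000.0

    def slice_indices(self) -> np.ndarray:
        """Indices of axial slices containing lesion voxels."""
        return np.flatnonzero(self.array.any(axis=(0, 1)))


def _affine(spacing_mm: Tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def save_nifti(obj: ImageVolume | RoiMask, path: str | Path) -> None:
    arr = obj.array
    if isinstance(obj, RoiMask):
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(arr), _affine(obj.spacing_mm))
    nib.save(img, str(path))


def load_volume(path: str | Path, sequence: Sequence = "T2W",
                patient_id: str = "", timepoint: Timepoint = "baseline") -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing,
                       sequence=sequence, patient_id=patient_id, timepoint=timepoint)


def load_mask(path: str | Path, patient_id: str = "",
              timepoint: Timepoint = "baseline") -> RoiMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return RoiMask(np.asarray(img.dataobj) > 0, spacing,
                   patient_id=patient_id, timepoint=timepoint)
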