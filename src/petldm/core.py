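"""Core volumetric containers and NIfTI I/O.

A :class:`Volume3D` is a 3D scalar grid (CT in Hounsfield units, PET in SUV,
or window-normalized CT) together with the voxel spacing in mm, an
orientation axis-code label (e.g. ``"RAS"``), and a modality tag.
:class:`Mask3D` is a binary grid aligned to a companion volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: Modality tags understood throughout the package.
CT_HU = "CT-HU"
PET_SUV = "PET-SUV"
CT_NORM = "normalized-CT"

_MODALITIES = (CT_HU, PET_SUV, CT_NORM)


@dataclass
class Volume3D:
    """A 3D scalar volume with geometry metadata.

    Parameters
    ----------
    values : ndarray
        3D array of voxel values.
    spacing : tuple of float
        Voxel spacing in mm along each array axis; strictly positive.
    orientation : str
        Three-letter axis-code label (nibabel convention), e.g. ``"RAS"``.
    modality : str
        One of ``"CT-HU"``, ``"PET-SUV"``, ``"normalized-CT"``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "RAS"
    modality: str = CT_HU

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "Volume3D":
        """Copy of self with new voxel data (and optionally a new modality)."""
        return replace(self, values=np.asarray(values, dtype=np.float32),
                       modality=self.modality if modality is None else modality)


@dataclass
class Mask3D:
    """A binary 3D grid aligned to a companion :class:`Volume3D`."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def aligned_with(self, other: "Volume3D | Mask3D") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and self.orientation == other.orientation)


@dataclass(frozen=True)
class CropBounds:
    """Per-axis half-open voxel index intervals ``[start, stop)``."""

    intervals: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        for lo, hi in self.intervals:
            if hi <= lo:
                raise ValueError(f"empty crop interval [{lo}, {hi})")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.intervals)


def _ras_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def save_volume(vol: Volume3D | Mask3D, path: str | Path) -> None:
    """Write a volume or mask as NIfTI with an RAS diagonal affine."""
    data = vol.values
    if isinstance(vol, Mask3D):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), _ras_affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_volume(path: str | Path, modality: str = CT_HU) -> Volume3D:
    """Read a NIfTI file as a :class:`Volume3D`.

    The orientation label is derived from the affine via nibabel axis codes.
    """
    img = nib.load(str(path))
    orientation = "".join(nib.aff2axcodes(img.affine))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(np.asanyarray(img.dataobj), spacing, orientation, modality)


def load_mask(path: str | Path) -> Mask3D:
    img = nib.load(str(path))
    orientation = "".join(nib.aff2axcodes(img.affine))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Mask3D(np.asanyarray(img.dataobj) > 0, spacing, orientation)
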