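"""Core containers: CT volumes in Hounsfield units and binary ROI masks.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)`` — slice index first;
* ``spacing`` is the physical voxel size ``(vs, vs, vz)`` in mm, stored as
  ``(vs_x, vs_y, vz)`` with square in-plane voxels (``vs_x == vs_y``);
* grey levels are Hounsfield units, rounded to the nearest integer whenever a
  volume leaves a processing step, mirroring CT convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["CTVolume", "ROIMask", "read_volume", "read_mask", "body_mask_from_hu"]


@dataclass
class CTVolume:
    """A 3D CT volume in HU with anisotropic voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, ny, nx)
        Grey levels in HU. Integer-valued after generation/resampling.
    spacing : tuple of float
        ``(vs_x, vs_y, vz)`` in mm; ``vs_x == vs_y``.
    case_id : str
        Stable case identifier.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    case_id: str = "case"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume.voxels must be 3D (z, y, x)")
        if self.voxels.shape[0] < 2:
            raise ValueError("CTVolume needs at least 2 slices")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing components must be strictly positive")
        self.spacing = sp

    @property
    def vs(self) -> float:
        """In-plane voxel size (mm)."""
        return self.spacing[0]

    @property
    def vz(self) -> float:
        """Slice spacing (mm)."""
        return self.spacing[2]

    def copy(self) -> "CTVolume":
        return CTVolume(self.voxels.copy(), self.spacing, self.case_id)


@dataclass
class ROIMask:
    """Binary region-of-interest mask aligned to a :class:`CTVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    label: str = "roi"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("ROIMask.voxels must be 3D (z, y, x)")
        sp = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in sp):
            raise ValueError("spacing components must be strictly positive")
        self.spacing = sp

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def copy(self) -> "ROIMask":
        return ROIMask(self.voxels.copy(), self.spacing, self.label)


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # arrays are (z, y, x); NIfTI is (i, j, k) fastest-first, so write x,y,z order
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


def write_volume(vol: CTVolume, path) -> None:
    img = nib.Nifti1Image(
        np.transpose(vol.voxels, (2, 1, 0)).astype(np.int16), _affine(vol.spacing)
    )
    nib.save(img, str(path))


def write_mask(mask: ROIMask, path) -> None:
    img = nib.Nifti1Image(
        np.transpose(mask.voxels, (2, 1, 0)).astype(np.uint8), _affine(mask.spacing)
    )
    nib.save(img, str(path))


def _load(path):
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    spacing = (float(zooms[0]), float(zooms[1]), float(zooms[2]))
    return data, spacing


def read_volume(path, case_id: str = "case") -> CTVolume:
    data, spacing = _load(path)
    return CTVolume(data.astype(np.int32), spacing, case_id)


def read_mask(path, label: str = "roi") -> ROIMask:
    data, spacing = _load(path)
    return ROIMask(data > 0, spacing, label)


def body_mask_from_hu(vol: CTVolume, threshold: float = -200.0) -> ROIMask:
    """Crude body segmentation: everything denser than `threshold` HU.

    Adequate for phantoms whose background is air; real scans would need hole
    filling and largest-component selection on top.
    """
    return ROIMask(vol.voxels > threshold, vol.spacing, label="body")
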