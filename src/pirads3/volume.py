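"""3D image and mask containers with physical voxel spacing.

Arrays are indexed ``(z, y, x)`` (slice-first, so ``voxels[k]`` is an axial
slice) while ``spacing`` and ``origin`` are ``(x, y, z)`` millimetre triples,
matching the NIfTI/ITK world-coordinate convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "MaskVolume", "read_nifti", "write_nifti", "read_nifti_mask"]


@dataclass
class ImageVolume:
    """A 3D scalar volume on a regular anisotropic grid.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Intensity values; must be finite.
    spacing : tuple of float
        Voxel size in mm as ``(x, y, z)``.
    origin : tuple of float
        World coordinate of the first voxel centre, mm ``(x, y, z)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ImageVolume | MaskVolume") -> bool:
        return (
            self.voxels.shape == other.voxels.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy_with(self, voxels: np.ndarray) -> "ImageVolume":
        return ImageVolume(np.asarray(voxels), self.spacing, self.origin)


@dataclass
class MaskVolume:
    """A binary region mask sharing the grid conventions of :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels) > 0
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def same_grid(self, other: "ImageVolume | MaskVolume") -> bool:
        return (
            self.voxels.shape == other.voxels.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_nifti(volume: ImageVolume | MaskVolume, path: str | Path) -> None:
    """Write a volume to a NIfTI file.

    The (z, y, x) array is transposed to the NIfTI (x, y, z) data layout and
    spacing/origin become a diagonal affine.
    """
    data = volume.voxels
    if isinstance(volume, MaskVolume):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.transpose(np.asarray(img.get_fdata(), dtype=np.float64), (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    origin = tuple(np.asarray(img.affine[:3, 3], dtype=float))
    return ImageVolume(data, (float(zooms[0]), float(zooms[1]), float(zooms[2])), origin)


def read_nifti_mask(path: str | Path) -> MaskVolume:
    vol = read_nifti(path)
    return MaskVolume(vol.voxels > 0.5, vol.spacing, vol.origin)
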