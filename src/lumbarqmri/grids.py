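"""Core image containers: scalar volumes, DWI series, and tensor fields.

All containers share one world-coordinate convention: RAS-like axes,
0-based voxel indices, and voxel-*center* world coordinates in mm.  The
affine is axis-aligned (diagonal spacing plus an origin translation);
oblique acquisitions are out of scope for this package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "DwiSeries", "TensorField", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


def _as_triple(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected a length-3 sequence, got {x!r}")
    return t


@dataclass
class ImageVolume:
    """A 3D scalar (or integer label) grid with spacing and origin.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values, axes ordered (x=right, y=anterior, z=superior).
    voxel_size_mm : (dx, dy, dz)
        Voxel spacing in mm, all > 0.
    origin_mm : (ox, oy, oz)
        World coordinate of the *center* of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume data must be 3-dimensional")
        self.voxel_size_mm = _as_triple(self.voxel_size_mm)
        self.origin_mm = _as_triple(self.origin_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        aff[:3, 3] = self.origin_mm
        return aff

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.data.shape[axis]
        return self.origin_mm[axis] + np.arange(n) * self.voxel_size_mm[axis]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk * np.asarray(self.voxel_size_mm) + np.asarray(self.origin_mm)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates (voxel (0,0,0) center -> (0,0,0))."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin_mm)) / np.asarray(self.voxel_size_mm)

    def same_grid(self, other: "ImageVolume", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    def like(self, data: np.ndarray) -> "ImageVolume":
        """A new volume on this grid holding `data`."""
        if data.shape != self.shape:
            raise GridMismatchError("data shape does not match grid")
        return ImageVolume(data, self.voxel_size_mm, self.origin_mm)

    # -- I/O --------------------------------------------------------------
    def save(self, path: str | os.PathLike) -> str:
        img = nib.Nifti1Image(np.asanyarray(self.data), self.affine)
        img.header.set_zooms(self.voxel_size_mm)
        nib.save(img, str(path))
        return str(path)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ImageVolume":
        img = nib.load(str(path))
        aff = img.affine
        if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
            raise ValueError("only axis-aligned (diagonal-affine) volumes are supported")
        spacing = tuple(np.diag(aff[:3, :3]))
        if any(s <= 0 for s in spacing):
            raise ValueError("negative or zero spacing in affine; RAS volumes expected")
        data = np.asanyarray(img.dataobj)
        return cls(data, spacing, tuple(aff[:3, 3]))


@dataclass
class DwiSeries:
    """4D diffusion-weighted stack plus gradient table.

    data has shape (nx, ny, nz, n_volumes); bvecs are unit direction rows
    (n_volumes, 3) and bvals are in s/mm².  Volumes with b=0 carry an
    arbitrary (ignored) direction.
    """

    data: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DwiSeries data must be 4-dimensional")
        n = self.data.shape[3]
        if self.bvals.shape != (n,) or self.bvecs.shape != (n, 3):
            raise ValueError("gradient table does not match number of volumes")
        weighted = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[weighted], axis=1)
        if weighted.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("weighted gradient directions must be unit vectors")
        self.voxel_size_mm = _as_triple(self.voxel_size_mm)
        self.origin_mm = _as_triple(self.origin_mm)

    @property
    def grid(self) -> ImageVolume:
        """A reference volume describing this series' grid."""
        return ImageVolume(
            np.zeros(self.data.shape[:3], dtype=np.uint8),
            self.voxel_size_mm,
            self.origin_mm,
        )

    def volume(self, index: int) -> ImageVolume:
        return ImageVolume(self.data[..., index], self.voxel_size_mm, self.origin_mm)

    # -- I/O: NIfTI + FSL bval/bvec text dialect ---------------------------
    def save(self, stem: str | os.PathLike) -> dict[str, str]:
        stem = str(stem)
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        aff[:3, 3] = self.origin_mm
        img = nib.Nifti1Image(self.data, aff)
        img.header.set_zooms(tuple(self.voxel_size_mm) + (1.0,))
        nii = stem + ".nii.gz"
        nib.save(img, nii)
        bval = stem + ".bval"
        bvec = stem + ".bvec"
        np.savetxt(bval, self.bvals[None, :], fmt="%.6g")
        np.savetxt(bvec, self.bvecs.T, fmt="%.17g")  # FSL: 3 rows x N cols
        return {"nifti": nii, "bval": bval, "bvec": bvec}

    @classmethod
    def load(cls, stem: str | os.PathLike) -> "DwiSeries":
        stem = str(stem)
        img = nib.load(stem + ".nii.gz")
        aff = img.affine
        spacing = tuple(np.diag(aff[:3, :3]))
        bvals = np.loadtxt(stem + ".bval").ravel()
        bvecs = np.loadtxt(stem + ".bvec").T
        return cls(np.asanyarray(img.dataobj), bvals, bvecs, spacing, tuple(aff[:3, 3]))


@dataclass
class TensorField:
    """Per-voxel symmetric 3×3 diffusion tensors (mm²/s) with validity mask.

    tensors has shape (nx, ny, nz, 3, 3); `valid` marks voxels holding a
    meaningful tensor; `s0` is the non-diffusion-weighted signal (may be
    None for synthetic ground truth).
    """

    tensors: np.ndarray
    valid: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    s0: np.ndarray | None = None

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.tensors.ndim != 5 or self.tensors.shape[3:] != (3, 3):
            raise ValueError("tensors must have shape (nx, ny, nz, 3, 3)")
        if self.valid.shape != self.tensors.shape[:3]:
            raise ValueError("valid mask shape mismatch")
        self.voxel_size_mm = _as_triple(self.voxel_size_mm)
        self.origin_mm = _as_triple(self.origin_mm)

    @property
    def grid(self) -> ImageVolume:
        return ImageVolume(
            np.zeros(self.tensors.shape[:3], dtype=np.uint8),
            self.voxel_size_mm,
            self.origin_mm,
        )
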