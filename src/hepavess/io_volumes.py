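"""Volume I/O, isotropic resampling, and liver-ROI cropping.

All volumes move through the pipeline as :class:`Volume3D` / :class:`BinaryMask3D`:
a scalar 3-D array plus voxel spacing (mm) and a 4x4 voxel-to-world affine.
Conventions used throughout the package:

* voxel indices are 0-based,
* crop boxes are half-open ``[lo, hi)``,
* intensity volumes are float32, masks are uint8 with values in {0, 1},
* intensity volumes are resampled with linear interpolation, masks with
  nearest-neighbour so they stay binary.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "Volume3D",
    "BinaryMask3D",
    "RoiBox",
    "VolumeIOError",
    "MissingVolumeError",
    "NotAVolumeError",
    "CorruptVolumeError",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "resample_isotropic",
    "liver_roi_box",
    "crop",
    "load_msd_case",
]


class VolumeIOError(Exception):
    """Base class for volume reading problems."""


class MissingVolumeError(VolumeIOError, FileNotFoundError):
    """The requested file does not exist."""


class NotAVolumeError(VolumeIOError, ValueError):
    """The file is a valid image but not a 3-D scalar volume."""


class CorruptVolumeError(VolumeIOError, ValueError):
    """The file exists but cannot be parsed as NIfTI."""


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclasses.dataclass
class Volume3D:
    """Scalar 3-D image with spacing (mm/voxel) and voxel-to-world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise NotAVolumeError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains NaN/Inf")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.spacing, self.affine.copy())


@dataclasses.dataclass
class BinaryMask3D:
    """3-D {0,1} mask sharing the grid of its paired :class:`Volume3D`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise NotAVolumeError(f"expected a 3-D array, got ndim={arr.ndim}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, found {vals[:10]}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "BinaryMask3D":
        return BinaryMask3D(self.data.copy(), self.spacing, self.affine.copy())


@dataclasses.dataclass(frozen=True)
class RoiBox:
    """Half-open voxel box ``[lo, hi)`` with the dilation margin that produced it."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    margin_vox: int = 0

    def __post_init__(self) -> None:
        if not all(l < h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate box lo={self.lo} hi={self.hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]


def read_volume(path: str | os.PathLike) -> Volume3D:
    """Read a NIfTI (.nii/.nii.gz) file as a float volume.

    Integer-typed files are promoted to float32. Raises
    :class:`MissingVolumeError`, :class:`NotAVolumeError` or
    :class:`CorruptVolumeError` for the three distinct failure modes.
    """
    path = Path(path)
    if not path.exists():
        raise MissingVolumeError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except MissingVolumeError:
        raise
    except Exception as exc:  # nibabel raises a zoo of error types
        raise CorruptVolumeError(f"cannot parse {path} as NIfTI: {exc}") from exc
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim != 3:
        raise NotAVolumeError(f"{path} is not a 3-D volume (ndim={data.ndim})")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    return Volume3D(np.ascontiguousarray(data), spacing, np.asarray(img.affine))


def read_mask(path: str | os.PathLike) -> BinaryMask3D:
    """Read a NIfTI file as a binary mask (any nonzero voxel -> 1)."""
    vol = read_volume(path)
    return BinaryMask3D((vol.data > 0.5).astype(np.uint8), vol.spacing, vol.affine)


def write_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask3D, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def _resample(data: np.ndarray, spacing, target_mm: float, order: int) -> np.ndarray:
    in_shape = np.array(data.shape)
    out_shape = np.maximum(1, np.round(in_shape * np.array(spacing) / target_mm)).astype(int)
    if np.array_equal(out_shape, in_shape) and np.allclose(spacing, target_mm):
        return data.copy()
    zoom = out_shape / in_shape
    return ndi.zoom(data, zoom, order=order, mode="nearest", grid_mode=True)


def resample_isotropic(
    vol: Volume3D | BinaryMask3D, target_mm: float = 1.0, interp: str | None = None
) -> Volume3D | BinaryMask3D:
    """Resample onto an isotropic ``target_mm`` grid.

    Output shape along each axis is ``round(shape * spacing / target_mm)`` so the
    world-space extent is preserved to within one voxel. Intensity volumes use
    linear interpolation; masks always use nearest-neighbour.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    is_mask = isinstance(vol, BinaryMask3D)
    if interp is None:
        interp = "nearest" if is_mask else "linear"
    if is_mask and interp != "nearest":
        raise ValueError("binary masks must be resampled with nearest interpolation")
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interp {interp!r}")
    order = 0 if interp == "nearest" else 1
    out = _resample(np.asarray(vol.data, dtype=np.float32), vol.spacing, target_mm, order)
    scale = np.array(vol.data.shape) / np.array(out.shape)
    affine = vol.affine.copy()
    affine[:3, :3] = affine[:3, :3] @ np.diag(scale)
    spacing = (target_mm,) * 3
    if is_mask:
        return BinaryMask3D((out > 0.5).astype(np.uint8), spacing, affine)
    return Volume3D(out.astype(np.float32), spacing, affine)


def liver_roi_box(mask: BinaryMask3D, margin_vox: int = 8) -> RoiBox:
    """Tight bounding box of the mask foreground, dilated by ``margin_vox``
    and clamped to the volume bounds."""
    if margin_vox < 0:
        raise ValueError("margin_vox must be >= 0")
    idx = np.nonzero(mask.data)
    if idx[0].size == 0:
        raise ValueError("empty mask: no foreground voxels")
    lo = tuple(max(0, int(a.min()) - margin_vox) for a in idx)
    hi = tuple(
        min(n, int(a.max()) + 1 + margin_vox) for a, n in zip(idx, mask.data.shape)
    )
    return RoiBox(lo, hi, margin_vox)


def crop(vol: Volume3D | BinaryMask3D, box: RoiBox) -> Volume3D | BinaryMask3D:
    """Extract ``[lo, hi)``; the affine is translated so world coordinates
    of retained voxels are unchanged."""
    if any(l < 0 for l in box.lo) or any(h > n for h, n in zip(box.hi, vol.data.shape)):
        raise ValueError(f"box {box.lo}..{box.hi} outside volume of shape {vol.data.shape}")
    out = vol.data[box.slices()].copy()
    affine = vol.affine.copy()
    affine[:3, 3] = (vol.affine @ np.array([*box.lo, 1.0]))[:3]
    cls = BinaryMask3D if isinstance(vol, BinaryMask3D) else Volume3D
    return cls(out, vol.spacing, affine)


def load_msd_case(root: str | os.PathLike, case: str) -> tuple[Volume3D, BinaryMask3D]:
    """Convenience loader for a Medical-Segmentation-Decathlon style layout
    (``imagesTr/<case>.nii.gz`` paired with ``labelsTr/<case>.nii.gz``).

    Entirely optional — nothing in the package requires external data.
    """
    root = Path(root)
    img = read_volume(root / "imagesTr" / f"{case}.nii.gz")
    lbl = read_mask(root / "labelsTr" / f"{case}.nii.gz")
    return img, lbl
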