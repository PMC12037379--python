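"""NIfTI-1 volume I/O and the canonical in-memory volume representation.

All volumes are reoriented to RAS+ at load time, voxel indices are 0-based
and world coordinates are millimetres.  Every downstream stage of the
pipeline (registration, subtraction, clustering, localization) operates on
:class:`PerfusionVolume` objects produced here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "PerfusionVolume",
    "BrainMask",
    "VolumeIOError",
    "NotAVolumeError",
    "InvalidAffineError",
    "read_volume",
    "write_volume",
    "voxel_volume_mm3",
]


class VolumeIOError(Exception):
    """Base class for volume I/O failures."""


class NotAVolumeError(VolumeIOError):
    """The file is not a single 3-D scalar volume."""


class InvalidAffineError(VolumeIOError):
    """The volume's voxel-to-world affine is not invertible."""


@dataclass
class PerfusionVolume:
    """A 3-D scalar field with voxel spacing and a world affine.

    Parameters
    ----------
    data
        3-D array of perfusion counts (arbitrary units) or any derived
        scalar map (difference image, z map).
    spacing
        Per-axis voxel size in mm, all components > 0.
    affine
        4x4 voxel-index -> world-mm map (RAS+ convention).
    frame_id
        Free-text provenance tag, e.g. ``"ictal"``, ``"interictal"``,
        ``"diff"`` or ``"zmap"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise NotAVolumeError(
                f"not a 3-D volume: data has {self.data.ndim} dimension(s)"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise InvalidAffineError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N, 3) 0-based voxel indices to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=np.float64))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (N, 3) world mm coordinates to fractional voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=np.float64))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def with_data(self, data: np.ndarray, frame_id: str | None = None) -> "PerfusionVolume":
        """Return a copy on the same grid carrying new voxel data."""
        return PerfusionVolume(
            data=np.asarray(data, dtype=np.float64),
            spacing=self.spacing,
            affine=self.affine.copy(),
            frame_id=self.frame_id if frame_id is None else frame_id,
        )


@dataclass
class BrainMask:
    """Binary voxel mask aligned to a parent :class:`PerfusionVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise NotAVolumeError("mask must be 3-D")
        if self.n_voxels == 0:
            raise ValueError("empty mask")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def read_volume(path: str | Path, frame_id: str = "") -> PerfusionVolume:
    """Load a single 3-D NIfTI-1 frame, reoriented to RAS+.

    Non-finite voxels (NaN/inf) are replaced by 0 with a logged warning;
    the sform affine is preferred over the qform when both are present.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    NotAVolumeError
        For 4-D or non-scalar images.
    InvalidAffineError
        If the header affine is singular.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        img = img.slicer[:, :, :, 0]
    elif len(shape) != 3:
        raise NotAVolumeError(f"not a 3-D volume: {path} has shape {shape}")
    # nibabel prefers sform over qform in get_affine resolution already;
    # reorient to RAS+ so left/right is unambiguous downstream.
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    bad = ~np.isfinite(data)
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("replaced %d non-finite voxel(s) with 0 in %s", n_bad, path)
        data[bad] = 0.0
    affine = np.asarray(img.affine, dtype=np.float64)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise InvalidAffineError(f"non-invertible affine in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not frame_id:
        descrip = img.header.get("descrip", b"")
        try:
            frame_id = bytes(descrip).decode("utf-8", "ignore").strip("\x00").strip()
        except Exception:
            frame_id = ""
    return PerfusionVolume(data=data, spacing=spacing, affine=affine, frame_id=frame_id)


def write_volume(vol: PerfusionVolume, path: str | Path) -> Path:
    """Write *vol* as NIfTI-1 (float32 data; frame_id in the descrip field)."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    if vol.frame_id:
        img.header["descrip"] = vol.frame_id.encode()[:79]
    nib.save(img, str(path))
    return path


def write_mask(mask: BrainMask, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit NIfTI-1 volume."""
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> BrainMask:
    """Load a binary NIfTI-1 mask (any nonzero voxel counts as true)."""
    vol = read_volume(path)
    return BrainMask(data=vol.data > 0, spacing=vol.spacing, affine=vol.affine)


def voxel_volume_mm3(vol: PerfusionVolume | BrainMask) -> float:
    """Volume of one voxel in mm^3 (product of the spacing components)."""
    sx, sy, sz = vol.spacing
    return float(sx * sy * sz)
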