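"""Core SISCOM arithmetic: masking, normalization, subtraction, z-scoring.

The subtraction workflow is: register the interictal scan to the ictal
grid, normalize both scans to a whole-brain mean of 100, subtract voxel
by voxel, convert the difference to z-scores using the mean and SD of the
differences over all brain voxels, and keep voxels whose |z| exceeds the
threshold (default 2).  Ictal hyperperfusion (z > +t) marks candidate
epileptogenic tissue; the two-sided mode also retains hypoperfusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import BrainMask, PerfusionVolume

__all__ = [
    "ZMap",
    "SignificanceMask",
    "DegenerateInputError",
    "compute_brain_mask",
    "normalize_global",
    "smooth_volume",
    "subtract",
    "zscore_map",
    "threshold_map",
]

NORMALIZATION_TARGET = 100.0  # conventional whole-brain global mean


class DegenerateInputError(ValueError):
    """Input volume is constant / empty where variation is required."""


@dataclass
class ZMap:
    """Z-scored difference map with the statistics that produced it."""

    data: np.ndarray
    mask: BrainMask
    mu_d: float
    sigma_d: float
    spacing: tuple[float, float, float] = None  # type: ignore[assignment]
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.spacing is None:
            self.spacing = self.mask.spacing
        if self.affine is None:
            self.affine = self.mask.affine
        if self.sigma_d <= 0:
            raise DegenerateInputError("sigma_d must be positive")

    def as_volume(self) -> PerfusionVolume:
        return PerfusionVolume(
            data=self.data, spacing=self.spacing, affine=self.affine, frame_id="zmap"
        )


@dataclass
class SignificanceMask:
    """Ternary significance grid: +1 hyper, -1 hypo, 0 nonsignificant."""

    data: np.ndarray
    threshold: float
    mode: str  # "positive-only" | "two-sided"
    spacing: tuple[float, float, float]
    affine: np.ndarray

    @property
    def n_significant(self) -> int:
        return int(np.count_nonzero(self.data))


def compute_brain_mask(
    vol: PerfusionVolume, threshold_fraction: float = 0.125
) -> BrainMask:
    """Threshold-based brain mask.

    Voxels brighter than ``threshold_fraction x global mean`` are kept,
    then only the largest 26-connected component survives, followed by a
    single 1-voxel morphological closing to fill surface pits.
    """
    data = vol.data
    if np.ptp(data) == 0:
        raise DegenerateInputError("constant volume: cannot compute a brain mask")
    thr = threshold_fraction * float(data.mean())
    rough = data > thr
    if not rough.any():
        raise DegenerateInputError("empty mask")
    structure = ndimage.generate_binary_structure(3, 3)  # 26-connectivity
    labels, n = ndimage.label(rough, structure=structure)
    if n > 1:
        sizes = ndimage.sum_labels(rough, labels, index=np.arange(1, n + 1))
        rough = labels == (int(np.argmax(sizes)) + 1)
    closed = ndimage.binary_closing(
        rough, structure=ndimage.generate_binary_structure(3, 1), iterations=1
    )
    keep = closed | rough  # closing must never erode the component
    return BrainMask(data=keep, spacing=vol.spacing, affine=vol.affine)


def normalize_global(vol: PerfusionVolume, mask: BrainMask) -> PerfusionVolume:
    """Proportionally scale so the in-mask mean equals 100.

    This is global-mean normalization of uptake toward the whole brain:
    the result is invariant to any positive rescaling of the input, which
    removes injected-dose and decay differences between the two sessions.
    """
    m = float(vol.data[mask.data].mean())
    if m <= 0:
        raise DegenerateInputError(f"nonpositive in-mask mean ({m}); cannot normalize")
    out = vol.data * (NORMALIZATION_TARGET / m)
    return vol.with_data(out)


def smooth_volume(vol: PerfusionVolume, fwhm_mm: float) -> PerfusionVolume:
    """Isotropic Gaussian smoothing with a FWHM given in mm."""
    if fwhm_mm <= 0:
        return vol
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / np.asarray(vol.spacing)
    return vol.with_data(ndimage.gaussian_filter(vol.data, sigma=sigma_vox))


def subtract(
    ictal_n: PerfusionVolume, interictal_n: PerfusionVolume, mask: BrainMask
) -> PerfusionVolume:
    """Voxel-wise difference (ictal - interictal), zero outside the mask."""
    if ictal_n.shape != interictal_n.shape or ictal_n.shape != mask.shape:
        raise ValueError(
            f"grid mismatch: {ictal_n.shape} vs {interictal_n.shape} vs {mask.shape}"
        )
    d = np.where(mask.data, ictal_n.data - interictal_n.data, 0.0)
    return ictal_n.with_data(d, frame_id="diff")


def zscore_map(diff: PerfusionVolume, mask: BrainMask) -> ZMap:
    """Z-score the difference using in-mask sample mean and SD (n-1).

    In-mask z values have mean 0 and SD 1 by construction; outside the
    mask the map is 0.
    """
    vals = diff.data[mask.data]
    if vals.size < 2:
        raise DegenerateInputError("need >= 2 in-mask voxels to z-score")
    mu = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0:
        raise DegenerateInputError("degenerate difference map (zero variance)")
    z = np.where(mask.data, (diff.data - mu) / sd, 0.0)
    return ZMap(data=z, mask=mask, mu_d=mu, sigma_d=sd)


def threshold_map(
    z: ZMap, threshold: float = 2.0, mode: str = "positive-only"
) -> SignificanceMask:
    """Mark voxels strictly exceeding the z threshold as significant.

    ``positive-only`` keeps hyperperfusion only (the EZ-localization
    default); ``two-sided`` additionally marks z < -threshold as -1.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if mode not in ("positive-only", "two-sided"):
        raise ValueError(f"unknown mode {mode!r}")
    out = np.zeros(z.data.shape, dtype=np.int8)
    inmask = z.mask.data
    out[inmask & (z.data > threshold)] = 1
    if mode == "two-sided":
        out[inmask & (z.data < -threshold)] = -1
    return SignificanceMask(
        data=out,
        threshold=float(threshold),
        mode=mode,
        spacing=z.spacing,
        affine=z.affine,
    )
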