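"""Synthetic ictal/interictal phantom pairs with known ground truth.

No public patient SPECT pairs exist for this workflow, so correctness is
demonstrated on digital phantoms: an ellipsoidal "brain" (outer gray
shell, dimmer inner white-matter ellipsoid) in which the ictal frame
carries a focal hyperperfusion sphere (the simulated epileptogenic zone)
plus optional propagation blobs.  Both frames are Gaussian-smoothed to
SPECT-like resolution; white Gaussian noise is added after smoothing; the
interictal frame can be rigidly misaligned by a known transform.  Every
quantity the pipeline estimates (registration transform, focus location,
cluster membership) is therefore known exactly.

The defaults approximate the study's acquisition regime: a ~3 mm
reconstructed grid, ~8 mm effective resolution, a mesial-temporal focus
with ~30% ictal hyperperfusion and a few-percent noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .registration import RigidTransform, resample
from .siscom_core import smooth_volume
from .volume_io import BrainMask, PerfusionVolume

__all__ = ["PhantomSpec", "GroundTruth", "make_phantom_pair", "make_cohort"]


@dataclass
class PhantomSpec:
    """Generator settings for one ictal/interictal phantom pair."""

    shape: tuple[int, int, int] = (64, 64, 56)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    brain_semiaxes_mm: tuple[float, float, float] = (65.0, 80.0, 60.0)
    gray_intensity: float = 100.0
    white_intensity: float = 60.0
    white_fraction: float = 0.55  # inner ellipsoid scale
    focus_center_mm: tuple[float, float, float] = (-42.0, -15.0, -8.0)
    focus_radius_mm: float = 12.0
    focus_amplitude_pct: float = 30.0  # % of local baseline, > 0
    propagation: list[tuple[tuple[float, float, float], float, float]] = field(
        default_factory=list
    )  # (center mm, radius mm, amplitude %)
    misalignment: RigidTransform = field(default_factory=RigidTransform.identity)
    noise_sd_pct: float = 5.0  # % of in-brain mean, post-smoothing
    smooth_fwhm_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape) or any(s <= 0 for s in self.spacing):
            raise ValueError("shape and spacing must be positive")
        if self.noise_sd_pct < 0:
            raise ValueError("noise_sd_pct must be >= 0")
        if self.focus_amplitude_pct < 0:
            raise ValueError("focus amplitude must be >= 0 (hyperperfusion)")
        for center, radius, _amp in [
            (self.focus_center_mm, self.focus_radius_mm, None),
            *self.propagation,
        ]:
            if not self._inside_brain(center, radius):
                raise ValueError(f"blob at {center} (r={radius}) outside brain ellipsoid")

    def _inside_brain(self, center, radius) -> bool:
        a = np.asarray(self.brain_semiaxes_mm, dtype=float)
        c = np.asarray(center, dtype=float)
        # conservative: blob center inside the ellipsoid shrunk by its radius
        return bool(np.sum((c / np.maximum(a - radius, 1e-6)) ** 2) <= 1.0)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must estimate."""

    ez_mask: BrainMask
    ez_side: str  # "left" | "right"
    applied_transform: RigidTransform
    propagation_masks: list[BrainMask] = field(default_factory=list)
    brain_mask: BrainMask | None = None


def _grid_affine(spec: PhantomSpec) -> np.ndarray:
    """RAS+ affine placing the world origin at the grid center."""
    A = np.diag([*spec.spacing, 1.0])
    A[:3, 3] = -(np.asarray(spec.shape) - 1) / 2.0 * np.asarray(spec.spacing)
    return A


def _world_grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    A = _grid_affine(spec)
    axes = [
        A[k, k] * np.arange(spec.shape[k]) + A[k, 3] for k in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _sphere_mask(spec: PhantomSpec, center, radius) -> np.ndarray:
    X, Y, Z = _world_grid(spec)
    cx, cy, cz = center
    return (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= radius**2


def _ellipsoid(X, Y, Z, center, semiaxes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def _baseline(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Brain-shaped baseline perfusion field.

    An outer gray ellipsoid with internal structure shared by both frames:
    a posteriorly offset white-matter core, two paramedian low-intensity
    "ventricles" and an infero-posterior cerebellum-like lobe.  The internal
    asymmetries matter: they give the joint histogram rotational contrast,
    without which mutual information cannot pin down rotations (a bare
    ellipsoid is nearly rotation-invariant).
    """
    X, Y, Z = _world_grid(spec)
    a = np.asarray(spec.brain_semiaxes_mm, dtype=float)
    brain = _ellipsoid(X, Y, Z, (0, 0, 0), a)
    base = np.zeros(spec.shape)
    base[brain] = spec.gray_intensity
    white = _ellipsoid(X, Y, Z, (0.0, -0.12 * a[1], 0.10 * a[2]), a * spec.white_fraction)
    base[white & brain] = spec.white_intensity
    cereb = _ellipsoid(
        X, Y, Z, (0.0, -0.55 * a[1], -0.55 * a[2]), (0.55 * a[0], 0.30 * a[1], 0.30 * a[2])
    )
    base[cereb & brain] = 1.12 * spec.gray_intensity
    for sx in (-1.0, 1.0):
        vent = _ellipsoid(
            X, Y, Z, (sx * 0.18 * a[0], -0.08 * a[1], 0.22 * a[2]),
            (0.10 * a[0], 0.38 * a[1], 0.14 * a[2]),
        )
        base[vent & brain] = 0.3 * spec.white_intensity
    return base, brain


def make_phantom_pair(
    spec: PhantomSpec,
) -> tuple[PerfusionVolume, PerfusionVolume, GroundTruth]:
    """Generate one (ictal, interictal, ground-truth) triple.

    The interictal frame is the smoothed noisy baseline rigidly moved by
    ``spec.misalignment`` (so that resampling it under that transform
    realigns it with the ictal grid); the ictal frame adds the focal and
    propagation hyperperfusion before smoothing.  Reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    affine = _grid_affine(spec)
    base, brain = _baseline(spec)

    focus = _sphere_mask(spec, spec.focus_center_mm, spec.focus_radius_mm)
    ictal_signal = base.copy()
    if spec.focus_amplitude_pct > 0:
        ictal_signal[focus] *= 1.0 + spec.focus_amplitude_pct / 100.0
    prop_masks = []
    for center, radius, amp in spec.propagation:
        pm = _sphere_mask(spec, center, radius)
        ictal_signal[pm] *= 1.0 + amp / 100.0
        prop_masks.append(BrainMask(data=pm, spacing=spec.spacing, affine=affine))

    def finish(signal: np.ndarray, frame_id: str, move: bool) -> PerfusionVolume:
        vol = PerfusionVolume(
            data=signal, spacing=spec.spacing, affine=affine, frame_id=frame_id
        )
        vol = smooth_volume(vol, spec.smooth_fwhm_mm)
        if move:
            vol = resample(vol, spec.misalignment.inverse(), vol)
        if spec.noise_sd_pct > 0:
            sd = spec.noise_sd_pct / 100.0 * float(vol.data[brain].mean())
            vol = vol.with_data(vol.data + rng.normal(0.0, sd, size=vol.data.shape))
        return vol

    ictal = finish(ictal_signal, "ictal", move=False)
    interictal = finish(base, "interictal", move=True)

    cx = spec.focus_center_mm[0]
    truth = GroundTruth(
        ez_mask=BrainMask(data=focus, spacing=spec.spacing, affine=affine),
        ez_side="right" if cx > 0 else "left",  # RAS+: +x is the right side
        applied_transform=spec.misalignment,
        propagation_masks=prop_masks,
        brain_mask=BrainMask(data=brain, spacing=spec.spacing, affine=affine),
    )
    return ictal, interictal, truth


def make_cohort(
    n: int,
    amplitudes_pct=(30.0,),
    noises_pct=(5.0,),
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
):
    """Generate a cohort of phantom pairs with randomized focus side.

    Amplitude and noise are drawn uniformly from the supplied grids; the
    focus side is mirrored in x for "right" patients.  Yields a manifest
    DataFrame and the per-patient (spec, ictal, interictal, truth) list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    amplitudes = list(amplitudes_pct)
    noises = list(noises_pct)
    if not amplitudes or not noises:
        raise ValueError("amplitude and noise grids must be non-empty")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    rows = []
    cohort = []
    for i in range(n):
        side = "right" if rng.random() < 0.5 else "left"
        amp = float(rng.choice(amplitudes))
        noise = float(rng.choice(noises))
        cx, cy, cz = base.focus_center_mm
        cx = abs(cx) if side == "right" else -abs(cx)
        pat_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            base,
            focus_center_mm=(cx, cy, cz),
            focus_amplitude_pct=amp,
            noise_sd_pct=noise,
            seed=pat_seed,
            propagation=[
                ((-c0, c1, c2), r, a) for (c0, c1, c2), r, a in base.propagation
            ]
            if side == "right"
            else list(base.propagation),
        )
        ictal, interictal, truth = make_phantom_pair(spec)
        cohort.append((spec, ictal, interictal, truth))
        rows.append(
            {
                "patient": i + 1,
                "side": side,
                "amplitude_pct": amp,
                "noise_pct": noise,
                "seed": pat_seed,
            }
        )
    return pd.DataFrame(rows), cohort
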