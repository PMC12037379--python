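"""Rigid-body coregistration of ictal and interictal volumes.

The similarity metric is mutual information (MI) of the joint intensity
histogram, the standard choice for intra-patient SPECT pairs whose tracer
uptake differs regionally between the two sessions.  The transform is a
6-parameter rigid body (3 translations in mm, 3 Euler rotations) optimized
by a derivative-free Powell search with a coarse-to-fine schedule.

Conventions
-----------
A :class:`RigidTransform` maps points in the *fixed* volume's world space
into the *moving* volume's world space:  ``y = R (x - c) + c + t``.
``resample(moving, T, fixed)`` therefore pulls the moving image onto the
fixed grid, which is how registration results are consumed downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .volume_io import BrainMask, PerfusionVolume

log = logging.getLogger(__name__)

__all__ = [
    "RigidTransform",
    "JointHistogram",
    "RegistrationResult",
    "RegistrationConfig",
    "InsufficientOverlapError",
    "mutual_information",
    "joint_histogram",
    "register_rigid",
    "resample",
]

MIN_OVERLAP_VOXELS = 1000


class InsufficientOverlapError(ValueError):
    """Fewer in-mask voxel pairs overlap than the metric requires."""


def _euler_to_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation matrix for extrinsic x-y-z Euler angles (radians)."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`_euler_to_matrix` (gimbal-safe for |ry| < 90 deg)."""
    ry = float(np.arcsin(np.clip(-R[2, 0], -1.0, 1.0)))
    if abs(np.cos(ry)) > 1e-8:
        rx = float(np.arctan2(R[2, 1], R[2, 2]))
        rz = float(np.arctan2(R[1, 0], R[0, 0]))
    else:  # degenerate; fold everything into rx
        rx = float(np.arctan2(-R[1, 2], R[1, 1]))
        rz = 0.0
    return rx, ry, rz


@dataclass
class RigidTransform:
    """6-parameter rigid map ``y = R (x - c) + c + t`` in world mm."""

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))  # radians, xyz
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @property
    def matrix(self) -> np.ndarray:
        """The induced 4x4 homogeneous world-to-world matrix."""
        R = _euler_to_matrix(*self.rotation)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = self.center + self.translation - R @ self.center
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform (N, 3) world points."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        R = _euler_to_matrix(*self.rotation)
        return (pts - self.center) @ R.T + self.center + self.translation

    def inverse(self) -> "RigidTransform":
        """The exact inverse transform, sharing this transform's center."""
        R = _euler_to_matrix(*self.rotation)
        Rinv = R.T
        # y = R(x-c)+c+t  =>  x = R^T(y-c)+c + (-R^T t)
        t_inv = -Rinv @ self.translation
        return RigidTransform(
            translation=t_inv,
            rotation=np.array(_matrix_to_euler(Rinv)),
            center=self.center.copy(),
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying *other* first, then *self*."""
        M = self.matrix @ other.matrix
        R = M[:3, :3]
        rot = np.array(_matrix_to_euler(R))
        # keep self's center; solve translation from the matrix offset
        c = self.center
        t = M[:3, 3] - c + R @ c
        return RigidTransform(translation=t, rotation=rot, center=c.copy())

    def to_dict(self) -> dict:
        return {
            "translation_mm": self.translation.tolist(),
            "rotation_deg": np.degrees(self.rotation).tolist(),
            "center_mm": self.center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            translation=np.asarray(d["translation_mm"], dtype=float),
            rotation=np.radians(np.asarray(d["rotation_deg"], dtype=float)),
            center=np.asarray(d.get("center_mm", np.zeros(3)), dtype=float),
        )


@dataclass
class JointHistogram:
    """B x B joint count grid over (fixed, moving) intensity bins."""

    counts: np.ndarray
    bin_edges_fixed: np.ndarray
    bin_edges_moving: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    def mutual_information(self) -> float:
        """MI in nats from the normalized joint histogram."""
        p = self.counts / max(self.counts.sum(), 1)
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        nz = p > 0
        return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))

    def entropy_fixed(self) -> float:
        px = self.counts.sum(axis=1) / max(self.counts.sum(), 1)
        nz = px > 0
        return float(-np.sum(px[nz] * np.log(px[nz])))


def _clip_range(data: np.ndarray, mask: np.ndarray | None = None) -> tuple[float, float]:
    vals = data[mask] if mask is not None else data.ravel()
    lo, hi = np.percentile(vals, [1.0, 99.0])
    if hi <= lo:
        lo, hi = float(vals.min()), float(vals.max() + 1e-9)
    return float(lo), float(hi)


def _sample_moving(
    moving: PerfusionVolume, world_pts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear samples of *moving* at world points; NaN marks outside."""
    vox = moving.world_to_voxel(world_pts)
    vals = ndimage.map_coordinates(
        moving.data, vox.T, order=1, mode="constant", cval=np.nan
    )
    return vals, np.isfinite(vals)


def joint_histogram(
    fixed: PerfusionVolume,
    moving: PerfusionVolume,
    transform: RigidTransform,
    bins: int = 64,
    mask: BrainMask | None = None,
) -> JointHistogram:
    """Joint intensity histogram of fixed vs transformed-moving voxels."""
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    sel = mask.data if mask is not None else np.ones(fixed.shape, dtype=bool)
    idx = np.argwhere(sel)
    fvals = fixed.data[sel]
    world = fixed.voxel_to_world(idx)
    mvals, ok = _sample_moving(moving, transform.apply(world))
    if int(ok.sum()) < MIN_OVERLAP_VOXELS:
        raise InsufficientOverlapError(
            f"only {int(ok.sum())} overlapping in-mask voxels (< {MIN_OVERLAP_VOXELS})"
        )
    # clip both marginals over the same voxel selection so that
    # MI(f, f, identity) reduces exactly to the marginal entropy H(f)
    f_lo, f_hi = _clip_range(fvals)
    m_lo, m_hi = _clip_range(mvals[ok])
    counts, ef, em = np.histogram2d(
        np.clip(fvals[ok], f_lo, f_hi),
        np.clip(mvals[ok], m_lo, m_hi),
        bins=bins,
        range=[[f_lo, f_hi], [m_lo, m_hi]],
    )
    return JointHistogram(counts=counts, bin_edges_fixed=ef, bin_edges_moving=em)


def mutual_information(
    fixed: PerfusionVolume,
    moving: PerfusionVolume,
    transform: RigidTransform | None = None,
    bins: int = 64,
    mask: BrainMask | None = None,
) -> float:
    """Mutual information (nats) between fixed and transformed moving volume."""
    transform = transform or RigidTransform.identity()
    return joint_histogram(fixed, moving, transform, bins=bins, mask=mask).mutual_information()


def resample(
    vol: PerfusionVolume,
    transform: RigidTransform,
    reference: PerfusionVolume,
) -> PerfusionVolume:
    """Trilinear resampling of *vol* onto the *reference* grid under *transform*.

    Voxels mapping outside the source volume are set to 0 (and should be
    excluded from downstream masks via the source-coverage convention).
    """
    # reference voxel -> reference world -> (T) source world -> source voxel
    A = np.linalg.inv(vol.affine) @ transform.matrix @ reference.affine
    out = ndimage.affine_transform(
        vol.data,
        A[:3, :3],
        offset=A[:3, 3],
        output_shape=reference.shape,
        order=1,
        mode="constant",
        cval=0.0,
    )
    return reference.with_data(out, frame_id=vol.frame_id)


@dataclass
class RegistrationConfig:
    bins: int = 64
    multires: bool = True
    coarse_spacing_mm: float = 6.0
    # metric smoothing (voxels) at full resolution: suppresses the
    # interpolation bias of MI on noisy images, where resampling at a
    # misaligned pose low-pass filters the noise and spuriously raises MI
    metric_smooth_vox: float = 1.0
    sample_stride: int = 2  # take every k-th in-mask voxel at full resolution
    xtol: float = 0.01
    maxiter: int = 40
    initial: RigidTransform | None = None


@dataclass
class RegistrationResult:
    transform: RigidTransform
    final_mi: float
    mi_at_identity: float
    converged: bool
    degraded: bool = False

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        doc = self.transform.to_dict() | {
            "final_mi_nats": self.final_mi,
            "mi_at_identity_nats": self.mi_at_identity,
            "converged": self.converged,
            "degraded": self.degraded,
        }
        path.write_text(json.dumps(doc, indent=2))
        return path


def _downsample(vol: PerfusionVolume, target_mm: float) -> PerfusionVolume:
    """Gaussian-smoothed pull-down to an approximately *target_mm* grid."""
    factors = np.maximum(np.array(vol.spacing) / target_mm, 1e-6)
    if np.all(factors >= 1.0):
        return vol
    k = 1.0 / factors  # step in source voxels per coarse voxel
    sigma = np.maximum((k - 1) / 2.0, 0.0)
    sm = ndimage.gaussian_filter(vol.data, sigma=sigma)
    new_shape = np.maximum((np.array(vol.shape) * factors).astype(int), 4)
    out = ndimage.affine_transform(
        sm, np.diag(k), offset=0.0, output_shape=tuple(new_shape), order=1,
        mode="constant", cval=0.0,
    )
    new_affine = vol.affine @ np.diag([k[0], k[1], k[2], 1.0])
    return PerfusionVolume(
        data=out,
        spacing=tuple(np.array(vol.spacing) * k),
        affine=new_affine,
        frame_id=vol.frame_id,
    )


def _mask_com_world(vol: PerfusionVolume, mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask)
    w = vol.data[mask]
    w = np.clip(w, 0, None) + 1e-12
    com_vox = (idx * w[:, None]).sum(axis=0) / w.sum()
    return vol.voxel_to_world(com_vox)[0]


def register_rigid(
    fixed: PerfusionVolume,
    moving: PerfusionVolume,
    config: RegistrationConfig | None = None,
    mask: BrainMask | None = None,
) -> RegistrationResult:
    """Estimate the rigid transform maximizing MI(fixed, moving o T).

    The search is a Powell coordinate-cycling descent over the 6 rigid
    parameters, run first on a coarse (~6 mm) grid and then refined at
    full resolution.  Initialization aligns the brain centers of mass;
    the rotation center is the fixed brain's center of mass, which
    decorrelates rotations from translations.

    If the optimizer fails to improve on the identity transform the
    identity is returned with ``degraded=True``.
    """
    from .siscom_core import compute_brain_mask  # deferred: avoids cycle

    config = config or RegistrationConfig()
    if mask is None:
        mask = compute_brain_mask(fixed)
    mask_m = compute_brain_mask(moving)

    center = _mask_com_world(fixed, mask.data)
    com_moving = _mask_com_world(moving, mask_m.data)
    if config.initial is not None:
        x0 = np.concatenate(
            [config.initial.translation, np.degrees(config.initial.rotation)]
        )
    else:
        x0 = np.concatenate([com_moving - center, np.zeros(3)])

    def make_objective(
        fx: PerfusionVolume,
        mv: PerfusionVolume,
        msk: BrainMask | None,
        x_init: np.ndarray,
        stride: int = 1,
    ):
        sel = msk.data if msk is not None else np.ones(fx.shape, bool)
        idx = np.argwhere(sel)[::stride]
        world = fx.voxel_to_world(idx)
        fvals = fx.data[tuple(idx.T)]
        f_lo, f_hi = _clip_range(fvals)
        # moving clip range from the in-mask samples at the initial pose:
        # a range estimated over a different voxel population would bin the
        # two marginals inconsistently and bias the MI optimum away from
        # the true alignment
        T0 = RigidTransform(
            translation=x_init[:3], rotation=np.radians(x_init[3:]), center=center
        )
        mv0, ok0 = _sample_moving(mv, T0.apply(world))
        m_lo, m_hi = _clip_range(mv0[ok0] if ok0.any() else mv.data)
        fclip = np.clip(fvals, f_lo, f_hi)

        def neg_mi(x: np.ndarray) -> float:
            T = RigidTransform(
                translation=x[:3], rotation=np.radians(x[3:]), center=center
            )
            mvals, ok = _sample_moving(mv, T.apply(world))
            if int(ok.sum()) < MIN_OVERLAP_VOXELS:
                return 0.0
            counts, _, _ = np.histogram2d(
                fclip[ok],
                np.clip(mvals[ok], m_lo, m_hi),
                bins=config.bins,
                range=[[f_lo, f_hi], [m_lo, m_hi]],
            )
            return -JointHistogram(counts, None, None).mutual_information()

        return neg_mi

    if config.metric_smooth_vox > 0:
        s = config.metric_smooth_vox
        fixed_m = fixed.with_data(ndimage.gaussian_filter(fixed.data, s))
        moving_m = moving.with_data(ndimage.gaussian_filter(moving.data, s))
    else:
        fixed_m, moving_m = fixed, moving

    levels: list[tuple[PerfusionVolume, PerfusionVolume, BrainMask | None, float]] = []
    if config.multires:
        fx_c = _downsample(fixed_m, config.coarse_spacing_mm)
        mv_c = _downsample(moving_m, config.coarse_spacing_mm)
        mk_c = compute_brain_mask(fx_c)
        levels.append((fx_c, mv_c, mk_c, config.xtol * 10))
    levels.append((fixed_m, moving_m, mask, config.xtol))

    x = x0.copy()
    converged = True
    for level, (fx, mv, mk, xtol) in enumerate(levels):
        fine = level == len(levels) - 1
        neg_mi = make_objective(fx, mv, mk, x, stride=config.sample_stride if fine else 1)
        res = optimize.minimize(
            neg_mi,
            x,
            method="Powell",
            options={"xtol": xtol, "ftol": 1e-6, "maxiter": config.maxiter},
        )
        x = res.x
        converged = converged and bool(res.success)
        if fine:
            # polish: restart Powell with small initial steps so the line
            # searches resolve the last few tenths of a mm / degree
            res = optimize.minimize(
                neg_mi,
                x,
                method="Powell",
                options={
                    "xtol": xtol / 10,
                    "ftol": 1e-10,
                    "maxiter": config.maxiter,
                    "direc": 0.15 * np.eye(6),
                },
            )
            x = res.x

    best = RigidTransform(translation=x[:3], rotation=np.radians(x[3:]), center=center)
    neg_mi_full = make_objective(fixed_m, moving_m, mask, x)
    final_mi = -neg_mi_full(x)
    mi_ident = -neg_mi_full(np.zeros(6))
    if final_mi < mi_ident:
        log.warning("registration failed to improve on identity; returning identity")
        return RegistrationResult(
            transform=RigidTransform(center=center),
            final_mi=mi_ident,
            mi_at_identity=mi_ident,
            converged=False,
            degraded=True,
        )
    return RegistrationResult(
        transform=best,
        final_mi=final_mi,
        mi_at_identity=mi_ident,
        converged=converged,
    )
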