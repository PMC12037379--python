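"""End-to-end SISCOM pipeline: register, normalize, subtract, z-score,
threshold, cluster, and (optionally) classify against a reference EZ mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cluster_analysis, localization, registration, siscom_core
from .cluster_analysis import ClusterSet
from .localization import ConcordanceLabel, EZReference
from .registration import RegistrationConfig, RegistrationResult, RigidTransform
from .siscom_core import SignificanceMask, ZMap
from .volume_io import BrainMask, PerfusionVolume

__all__ = ["SiscomConfig", "SiscomResult", "run_siscom"]


@dataclass
class SiscomConfig:
    z_threshold: float = 2.0
    mode: str = "positive-only"  # or "two-sided"
    connectivity: int = 26
    adjacency_mm: float = localization.DEFAULT_ADJACENCY_MM
    smooth_fwhm_mm: float = 0.0  # optional pre-subtraction smoothing
    register: bool = True
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)

    def to_dict(self) -> dict:
        return {
            "z_threshold": self.z_threshold,
            "mode": self.mode,
            "connectivity": self.connectivity,
            "adjacency_mm": self.adjacency_mm,
            "smooth_fwhm_mm": self.smooth_fwhm_mm,
            "register": self.register,
            "bins": self.registration.bins,
            "multires": self.registration.multires,
        }


@dataclass
class SiscomResult:
    registration: RegistrationResult | None
    brain_mask: BrainMask
    zmap: ZMap
    significance: SignificanceMask
    clusters: ClusterSet
    labels: dict[str, ConcordanceLabel | None] | None
    report: dict


def run_siscom(
    ictal: PerfusionVolume,
    interictal: PerfusionVolume,
    ez: EZReference | None = None,
    config: SiscomConfig | None = None,
) -> SiscomResult:
    """Run the full subtraction workflow on one ictal/interictal pair.

    All derived maps live on the ictal grid; the z statistics are computed
    over the intersection of the two volumes' brain masks (restricted to
    voxels covered by the resampled interictal scan).
    """
    config = config or SiscomConfig()

    reg: RegistrationResult | None = None
    if config.register:
        reg = registration.register_rigid(
            ictal, interictal, config=config.registration
        )
        transform = reg.transform
    else:
        transform = RigidTransform.identity()
    inter_on_ictal = registration.resample(interictal, transform, ictal)

    mask_i = siscom_core.compute_brain_mask(ictal)
    mask_j = siscom_core.compute_brain_mask(inter_on_ictal)
    both = mask_i.data & mask_j.data & (inter_on_ictal.data != 0)
    mask = BrainMask(data=both, spacing=ictal.spacing, affine=ictal.affine)

    ictal_n = siscom_core.normalize_global(ictal, mask)
    inter_n = siscom_core.normalize_global(inter_on_ictal, mask)
    if config.smooth_fwhm_mm > 0:
        ictal_n = siscom_core.smooth_volume(ictal_n, config.smooth_fwhm_mm)
        inter_n = siscom_core.smooth_volume(inter_n, config.smooth_fwhm_mm)

    diff = siscom_core.subtract(ictal_n, inter_n, mask)
    zmap = siscom_core.zscore_map(diff, mask)
    sig = siscom_core.threshold_map(zmap, config.z_threshold, config.mode)
    clusters = cluster_analysis.label_clusters(sig, zmap, config.connectivity)

    labels = None
    if ez is not None:
        labels = localization.evaluate_patient(
            clusters, zmap, ez, adjacency_mm=config.adjacency_mm
        )

    report = {
        "config": config.to_dict(),
        "mu_d": zmap.mu_d,
        "sigma_d": zmap.sigma_d,
        "mask_voxels": mask.n_voxels,
        "n_significant": sig.n_significant,
        "clusters": cluster_analysis.cluster_report(clusters),
    }
    if reg is not None:
        report["registration"] = reg.transform.to_dict() | {
            "final_mi_nats": reg.final_mi,
            "converged": reg.converged,
            "degraded": reg.degraded,
        }
    if labels is not None:
        report["labels"] = {
            k: (None if v is None else {"label": v.value.value, "distance_mm": v.distance_mm})
            for k, v in labels.items()
        }
    return SiscomResult(
        registration=reg,
        brain_mask=mask,
        zmap=zmap,
        significance=sig,
        clusters=clusters,
        labels=labels,
        report=report,
    )
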