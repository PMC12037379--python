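"""Epileptogenic-zone concordance of SISCOM clusters with a reference mask.

Four localization criteria are evaluated per study: the cluster holding
the highest-intensity voxel, and the first, second and third largest
clusters.  Each candidate is labelled against the reference EZ region:

- ``concordant`` — the cluster overlaps the reference mask (>= 1 voxel);
- ``partially_concordant`` — no overlap, but the minimum boundary
  distance is within the adjacency radius (default 10 mm);
- ``discordant`` — farther than the adjacency radius.

For group statistics, partially-concordant and discordant collapse into
a single non-concordant class.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .cluster_analysis import Cluster, ClusterSet, highest_intensity_voxel
from .siscom_core import ZMap
from .volume_io import BrainMask

__all__ = [
    "Concordance",
    "ConcordanceLabel",
    "EZReference",
    "CRITERIA",
    "classify_cluster",
    "evaluate_patient",
    "binarize_labels",
    "sensitivity",
]

DEFAULT_ADJACENCY_MM = 10.0

CRITERIA = ("highest_intensity", "cluster1", "cluster2", "cluster3")


class Concordance(str, Enum):
    CONCORDANT = "C"
    PARTIALLY_CONCORDANT = "PC"
    DISCORDANT = "D"


@dataclass
class ConcordanceLabel:
    value: Concordance
    criterion: str
    distance_mm: float  # 0 for overlap; else min boundary distance


@dataclass
class EZReference:
    """Reference epileptogenic-zone region (e.g. resection area)."""

    mask: BrainMask
    side: str  # "left" | "right"
    lobe: str = "temporal"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    def world_coords(self) -> np.ndarray:
        idx = np.argwhere(self.mask.data)
        A = np.asarray(self.mask.affine)
        return idx @ A[:3, :3].T + A[:3, 3]


def classify_cluster(
    cluster: Cluster,
    ez: EZReference,
    adjacency_mm: float = DEFAULT_ADJACENCY_MM,
    criterion: str = "",
) -> ConcordanceLabel:
    """Label one cluster against the reference EZ mask.

    Overlap (any shared voxel) wins immediately; otherwise the minimum
    Euclidean distance between cluster voxels and EZ voxels in world mm
    decides between partially concordant and discordant.
    """
    ez_idx = np.argwhere(ez.mask.data)
    flat_ez = set(map(tuple, ez_idx))
    if any(tuple(v) in flat_ez for v in cluster.voxel_indices):
        return ConcordanceLabel(Concordance.CONCORDANT, criterion, 0.0)
    tree = cKDTree(ez.world_coords())
    A = np.asarray(ez.mask.affine)
    cl_world = cluster.voxel_indices @ A[:3, :3].T + A[:3, 3]
    dist = float(tree.query(cl_world)[0].min())
    if dist <= adjacency_mm:
        return ConcordanceLabel(Concordance.PARTIALLY_CONCORDANT, criterion, dist)
    return ConcordanceLabel(Concordance.DISCORDANT, criterion, dist)


def evaluate_patient(
    cs: ClusterSet,
    z: ZMap,
    ez: EZReference,
    adjacency_mm: float = DEFAULT_ADJACENCY_MM,
) -> dict[str, ConcordanceLabel | None]:
    """Apply all four EZ criteria; missing clusters yield None labels."""
    labels: dict[str, ConcordanceLabel | None] = {c: None for c in CRITERIA}
    pos = cs.by_sign(1)
    if not pos:
        return labels
    _, _, hi_rank = highest_intensity_voxel(cs, z)
    labels["highest_intensity"] = classify_cluster(
        cs.clusters[hi_rank], ez, adjacency_mm, "highest_intensity"
    )
    for k, name in enumerate(("cluster1", "cluster2", "cluster3")):
        if k < len(pos):
            labels[name] = classify_cluster(pos[k], ez, adjacency_mm, name)
    return labels


def binarize_labels(labels) -> list:
    """Concordant -> 1; partially concordant / discordant -> 0; None kept.

    Accepts ConcordanceLabel objects, Concordance values, or the string
    codes "C"/"PC"/"D".
    """
    out = []
    for lab in labels:
        if lab is None:
            out.append(None)
            continue
        if isinstance(lab, ConcordanceLabel):
            lab = lab.value
        code = lab.value if isinstance(lab, Concordance) else str(lab)
        if code not in ("C", "PC", "D"):
            raise ValueError(f"unknown concordance code {code!r}")
        out.append(1 if code == "C" else 0)
    return out


def sensitivity(binary) -> float:
    """Concordant fraction among non-missing labels."""
    vals = [b for b in binary if b is not None]
    if not vals:
        raise ValueError("all labels missing")
    return float(sum(vals)) / len(vals)
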