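"""Connected-component cluster extraction and ranking on significance maps.

A cluster is a connected set of suprathreshold voxels of one sign class.
Clusters are ranked by voxel count (volume) — the candidate epileptogenic
zone is, depending on the criterion, the cluster containing the global
peak z, or the 1st/2nd/3rd largest cluster.  Sizes are reported in mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .siscom_core import SignificanceMask, ZMap
from .volume_io import voxel_volume_mm3

__all__ = [
    "Cluster",
    "ClusterSet",
    "NoSignificantVoxelsError",
    "label_clusters",
    "rank_clusters",
    "highest_intensity_voxel",
    "cluster_report",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


class NoSignificantVoxelsError(ValueError):
    """The significance mask contains no suprathreshold voxels."""


@dataclass(eq=False)
class Cluster:
    voxel_indices: np.ndarray  # (n, 3) int array
    n_voxels: int
    volume_mm3: float
    peak_z: float
    peak_index: tuple[int, int, int]
    centroid_mm: np.ndarray
    sign: int

    def contains(self, index: tuple[int, int, int]) -> bool:
        return bool((self.voxel_indices == np.asarray(index)).all(axis=1).any())


@dataclass
class ClusterSet:
    clusters: list[Cluster] = field(default_factory=list)
    global_peak_index: tuple[int, int, int] | None = None
    global_peak_z: float | None = None
    voxel_volume: float = 1.0

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def by_sign(self, sign: int) -> list[Cluster]:
        return [c for c in self.clusters if c.sign == sign]


def _extract_sign(
    sig: SignificanceMask, z: ZMap, sign: int, structure: np.ndarray, vox_mm3: float
) -> list[Cluster]:
    binary = sig.data == sign
    labels, n = ndimage.label(binary, structure=structure)
    clusters: list[Cluster] = []
    if n == 0:
        return clusters
    zdata = z.data if sign > 0 else -z.data  # peak = extreme in the sign's direction
    affine = np.asarray(sig.affine)
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        zv = zdata[tuple(idx.T)]
        k = int(np.argmax(zv))
        w = zv - zv.min() + 1e-12
        centroid_vox = (idx * w[:, None]).sum(axis=0) / w.sum()
        centroid_mm = centroid_vox @ affine[:3, :3].T + affine[:3, 3]
        clusters.append(
            Cluster(
                voxel_indices=idx,
                n_voxels=len(idx),
                volume_mm3=len(idx) * vox_mm3,
                peak_z=float(z.data[tuple(idx[k])]),
                peak_index=tuple(int(v) for v in idx[k]),
                centroid_mm=centroid_mm,
                sign=sign,
            )
        )
    return clusters


def label_clusters(
    sig: SignificanceMask, z: ZMap, connectivity: int = 26
) -> ClusterSet:
    """Connected components of the significance mask, per sign class.

    An empty mask yields an empty ClusterSet (not an error).  Default
    connectivity is 26 (face + edge + corner neighbours).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    if sig.data.shape != z.data.shape:
        raise ValueError("significance mask and z map are on different grids")
    structure = _STRUCTURES[connectivity]
    vox = float(np.prod(sig.spacing))
    clusters = _extract_sign(sig, z, 1, structure, vox)
    if sig.mode == "two-sided":
        clusters += _extract_sign(sig, z, -1, structure, vox)
    cs = ClusterSet(clusters=clusters, voxel_volume=vox)
    pos = np.argwhere(sig.data == 1)
    if len(pos):
        zp = z.data[tuple(pos.T)]
        k = int(np.argmax(zp))
        cs.global_peak_index = tuple(int(v) for v in pos[k])
        cs.global_peak_z = float(zp[k])
    return rank_clusters(cs)


def rank_clusters(cs: ClusterSet) -> ClusterSet:
    """Sort clusters by descending voxel count.

    Ties break toward higher peak z, then lexicographically smaller peak
    index, so the ordering is fully deterministic.
    """
    cs.clusters.sort(key=lambda c: (-c.n_voxels, -c.peak_z, c.peak_index))
    return cs


def highest_intensity_voxel(
    cs: ClusterSet, z: ZMap
) -> tuple[tuple[int, int, int], float, int]:
    """Global z maximum over significant hyperperfusion voxels.

    Returns ``(voxel index, z value, rank of the containing cluster)``
    where rank is the 0-based position in the volume-ordered cluster list.
    """
    pos = cs.by_sign(1)
    if not pos:
        raise NoSignificantVoxelsError("no significant voxels")
    best = max(pos, key=lambda c: c.peak_z)
    rank = next(i for i, c in enumerate(cs.clusters) if c is best)
    return best.peak_index, best.peak_z, rank


def cluster_report(cs: ClusterSet) -> dict:
    """Per-study cluster summary mirroring the quantitative results schema.

    Fields: highest intensity (peak z), number of hyperperfusion clusters,
    and the volumes (mm^3) of the three largest clusters; absent entries
    are None.
    """
    pos = cs.by_sign(1)
    vols = [c.volume_mm3 for c in pos]
    report = {
        "highest_intensity": max((c.peak_z for c in pos), default=None),
        "n_clusters": len(pos),
        "vol1_mm3": vols[0] if len(vols) > 0 else None,
        "vol2_mm3": vols[1] if len(vols) > 1 else None,
        "vol3_mm3": vols[2] if len(vols) > 2 else None,
    }
    return report
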