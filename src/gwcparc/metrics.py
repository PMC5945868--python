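"""Parcellation quality criteria: contiguity, homogeneity, reproducibility.

* Spatial discontiguity index — label the 26-connected components inside
  each cluster; the excess of total components over the cluster count.
  0 means every cluster is one spatially connected piece.

* Functional homogeneity — within each cluster, the mean Pearson
  correlation over all ordered pairs of distinct voxel time courses,
  averaged (unweighted) over clusters with at least two voxels; singleton
  clusters are omitted and counted. Computed in O(N T) via the identity
  sum_{i != j} z_i . z_j = ||sum_i z_i||^2 - sum_i ||z_i||^2 on unit-norm
  demeaned series.

* Dice coefficient — overlap of the same-cluster voxel-pair sets of two
  atlases. With contingency counts n_uv between the clusters of A and B,
  Dice = 2 sum n_uv^2 / (sum n_u.^2 + sum n_.v^2); this equals the
  adjacency-matrix form (diagonal included) without materializing N0 x N0
  matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import ndimage

from .io import Atlas, BoldVolume, BrainMask, mask_coords
from .supervoxels import zscore_series
from .synthetic import STRUCT_26

__all__ = [
    "EvalReport",
    "spatial_discontiguity_index",
    "functional_homogeneity",
    "dice_coefficient",
    "cross_subject_homogeneity",
    "subject_pair_count",
]


def subject_pair_count(n_subjects: int) -> int:
    """Number of unordered subject pairs available for reproducibility, C(n, 2).

    Reproducibility studies average the Dice coefficient over (a sample of)
    these pairs; e.g. a 36-subject cohort offers 630 pairs.
    """
    if n_subjects < 2:
        raise ValueError("need at least two subjects")
    return n_subjects * (n_subjects - 1) // 2


@dataclass
class EvalReport:
    discontiguity_index: int | None = None
    homogeneity: float | None = None
    per_cluster_homogeneity: np.ndarray | None = None
    n_singletons_omitted: int = 0
    dice: float | None = None


def spatial_discontiguity_index(atlas: Atlas) -> int:
    """Total within-cluster 26-connected components minus the cluster count."""
    total = 0
    labels = np.unique(atlas.labels[atlas.labels > 0])
    for lab in labels:
        _, ncomp = ndimage.label(atlas.labels == lab, structure=STRUCT_26)
        total += ncomp
    return int(total - labels.size)


def functional_homogeneity(
    atlas: Atlas, volume: BoldVolume, mask: BrainMask
) -> tuple[float, np.ndarray, int]:
    """(overall homogeneity, per-cluster values, singleton count)."""
    if atlas.labels.shape != mask.data.shape:
        raise ValueError("atlas and mask grids differ")
    coords = mask_coords(mask)
    series = volume.data[coords[:, 0], coords[:, 1], coords[:, 2], :]
    lab = atlas.labels[coords[:, 0], coords[:, 1], coords[:, 2]]
    if (lab == 0).any():
        # atlas may cover a sub-mask; evaluate on labeled voxels only
        keep = lab > 0
        series, lab = series[keep], lab[keep]
    z = zscore_series(series)
    z /= np.sqrt(z.shape[1])  # unit-norm rows; corr_ij = z_i . z_j
    per_cluster = []
    n_singleton = 0
    for c in np.unique(lab):
        members = lab == c
        n = int(members.sum())
        if n < 2:
            n_singleton += 1
            continue
        zc = z[members]
        total = float(np.dot(zc.sum(axis=0), zc.sum(axis=0)) - (zc * zc).sum())
        per_cluster.append(total / (n * (n - 1)))
    if not per_cluster:
        raise ValueError("all clusters are singletons; homogeneity undefined")
    per_cluster = np.asarray(per_cluster)
    return float(per_cluster.mean()), per_cluster, n_singleton


def dice_coefficient(atlas_a: Atlas, atlas_b: Atlas) -> float:
    """Adjacency-overlap Dice between two atlases on the same mask."""
    ma, mb = atlas_a.labels > 0, atlas_b.labels > 0
    if not np.array_equal(ma, mb):
        raise ValueError("atlases are defined on different masks")
    a = atlas_a.labels[ma]
    b = atlas_b.labels[mb]
    cont = sp.coo_matrix(
        (np.ones(a.size), (a - 1, b - 1)),
        shape=(int(a.max()), int(b.max())),
    ).toarray()
    inter = float((cont**2).sum())
    sa = float((cont.sum(axis=1) ** 2).sum())
    sb = float((cont.sum(axis=0) ** 2).sum())
    return 2.0 * inter / (sa + sb)


def cross_subject_homogeneity(
    atlas_from: Atlas, volumes_other: list[tuple[BoldVolume, BrainMask]]
) -> float:
    """Homogeneity of one atlas averaged over held-out subjects' data."""
    if not volumes_other:
        raise ValueError("no held-out volumes provided")
    vals = [functional_homogeneity(atlas_from, vol, msk)[0] for vol, msk in volumes_other]
    return float(np.mean(vals))
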