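"""Competing parcellation approaches and their randomized null variants.

Two voxel-level normalized-cut baselines and a supervoxel-as-atlas baseline:

* Ncut with the spatially constrained correlation weight
      w_ij = corr(v_i, v_j)  if ||u_i - u_j|| <= 3 (voxel units), else 0
  (negative correlations retained in W, clipped at the embedding step);

* Ncut with the dense Gaussian weight
      w_ij = exp(-||v_i - v_j||^2 / sigma_v^2 - ||u_i - u_j||^2 / sigma_u^2)
  with sigma_v, sigma_u the medians of the pairwise functional and spatial
  distances (subsampled when the pair count is large);

* SLIC with n_supervoxels = K: the supervoxels themselves are the clusters.

Null variants destroy the data's spatial organization while keeping the
algorithm and parameters fixed: Ncut runs on an edge-permuted weight matrix;
SLIC and the graph-learning pipeline run on spatially permuted time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .gwc import GwcParams, parcellate
from .io import Atlas, BoldVolume, BrainMask, labels_to_atlas, mask_coords, mask_series
from .spectral import spectral_cluster
from .supervoxels import SlicParams, run_slic, zscore_series
from .synthetic import permute_time_series, permute_weight_matrix

__all__ = [
    "WeightMatrix",
    "weights_constrained_corr",
    "weights_gaussian",
    "ncut_parcellate",
    "slic_parcellate",
    "random_variant",
]


@dataclass
class WeightMatrix:
    """Symmetric voxel-pair weights with the scheme that produced them."""

    W: object  # dense ndarray or scipy.sparse matrix
    scheme: str  # 'constrained_corr' | 'gaussian'


def weights_constrained_corr(volume: BoldVolume, mask: BrainMask) -> WeightMatrix:
    """Pearson-correlation weights between voxels within radius 3 (voxel units)."""
    coords = mask_coords(mask)
    z = zscore_series(mask_series(volume, mask))
    z /= np.sqrt(z.shape[1])  # corr = dot product
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=3.0 + 1e-9, output_type="ndarray")
    w = (z[pairs[:, 0]] * z[pairs[:, 1]]).sum(axis=1)
    n0 = coords.shape[0]
    W = sp.coo_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([pairs[:, 0], pairs[:, 1]]),
          np.concatenate([pairs[:, 1], pairs[:, 0]]))),
        shape=(n0, n0),
    ).tocsr()
    return WeightMatrix(W=W, scheme="constrained_corr")


def _median_distance(points: np.ndarray, max_pairs: int = 10**6, seed: int = 0) -> float:
    """Median pairwise Euclidean distance, subsampled beyond ``max_pairs`` pairs."""
    n = points.shape[0]
    n_pairs = n * (n - 1) // 2
    if n_pairs <= max_pairs:
        return float(np.median(pdist(points)))
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=max_pairs)
    j = rng.integers(0, n, size=max_pairs)
    keep = i != j
    d = np.linalg.norm(points[i[keep]] - points[j[keep]], axis=1)
    return float(np.median(d))


def weights_gaussian(volume: BoldVolume, mask: BrainMask, seed: int = 0) -> WeightMatrix:
    """Dense Gaussian weights on functional and spatial distance."""
    coords = mask_coords(mask).astype(float)
    if coords.shape[0] < 2:
        raise ValueError("need at least two in-mask voxels")
    series = mask_series(volume, mask)
    sigma_v = _median_distance(series, seed=seed)
    sigma_u = _median_distance(coords, seed=seed)

    sq = (series * series).sum(axis=1)
    dv2 = sq[:, None] + sq[None, :] - 2.0 * (series @ series.T)
    np.maximum(dv2, 0.0, out=dv2)
    if sigma_v <= 0:
        warnings.warn("all time courses identical; functional term set to 1")
        dv2[:] = 0.0
    else:
        dv2 /= -(sigma_v**2)
    squ = (coords * coords).sum(axis=1)
    du2 = squ[:, None] + squ[None, :] - 2.0 * (coords @ coords.T)
    np.maximum(du2, 0.0, out=du2)
    du2 /= -(sigma_u**2)
    dv2 += du2
    del du2
    W = np.exp(dv2, out=dv2)
    np.fill_diagonal(W, 0.0)
    return WeightMatrix(W=0.5 * (W + W.T), scheme="gaussian")


def ncut_parcellate(
    W: WeightMatrix | np.ndarray, K: int, mask: BrainMask, seed: int = 0, affine=None
) -> Atlas:
    """Normalized-cut spectral clustering of a voxel weight matrix."""
    mat = W.W if isinstance(W, WeightMatrix) else W
    labels = spectral_cluster(mat, K, seed=seed)
    return labels_to_atlas(labels, mask, affine=affine)


def slic_parcellate(
    volume: BoldVolume, mask: BrainMask, K: int, m: float = 10.0, seed: int = 0
) -> Atlas:
    """SLIC supervoxels used directly as the atlas (n_supervoxels = K)."""
    sv = run_slic(volume, mask, SlicParams(n_supervoxels=K, m=m, seed=seed))
    coords = mask_coords(mask)
    flat = sv.labels[coords[:, 0], coords[:, 1], coords[:, 2]]
    return labels_to_atlas(flat, mask, affine=volume.affine)


def random_variant(
    approach: str,
    volume: BoldVolume,
    mask: BrainMask,
    K: int,
    seed: int = 0,
    *,
    weight_scheme: str = "gaussian",
    m: float = 10.0,
    slic_params: SlicParams | None = None,
    gwc_params: GwcParams | None = None,
) -> Atlas:
    """Run the named approach on randomized data with identical parameters.

    'ncut' permutes the voxel weight matrix; 'slic' and 'gwc' permute the
    spatial assignment of the time series.
    """
    if approach == "ncut":
        builder = weights_gaussian if weight_scheme == "gaussian" else (
            lambda v, mk: weights_constrained_corr(v, mk)
        )
        wm = builder(volume, mask)
        Wrand = permute_weight_matrix(wm.W, seed=seed)
        return ncut_parcellate(Wrand, K, mask, seed=seed, affine=volume.affine)
    if approach == "slic":
        rnd = permute_time_series(volume, mask, seed=seed)
        return slic_parcellate(rnd, mask, K, m=m, seed=seed)
    if approach == "gwc":
        rnd = permute_time_series(volume, mask, seed=seed)
        atlas, _ = parcellate(rnd, mask, slic_params=slic_params,
                              gwc_params=gwc_params)
        return atlas
    raise ValueError(f"unknown approach: {approach!r}")
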