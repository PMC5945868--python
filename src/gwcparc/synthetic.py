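"""Phantom generation and the null (randomization) procedures.

The phantom emulates a masked 3D grid partitioned into spatially contiguous
functional parcels: each parcel carries one latent time course and every
member voxel observes that course plus i.i.d. Gaussian noise. It stands in
for a preprocessed single-subject resting-state acquisition so that every
stage of the pipeline — supervoxels, graph learning, metrics, baselines —
is testable without real data.

The two permutation procedures implement the null models used to probe
whether a parcellation approach relies on spatial structure alone:
``permute_time_series`` scrambles which voxel owns which time course (for
the supervoxel-based approaches), and ``permute_weight_matrix`` scrambles
the edges of a voxel-wise weight matrix (for the spectral baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import Atlas, BoldVolume, BrainMask, mask_coords

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "permute_time_series",
    "permute_weight_matrix",
]

#: 26-connectivity structuring element used throughout the package.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PhantomSpec:
    """Recipe for a planted-parcel phantom.

    Parameters
    ----------
    shape : grid dimensions (nx, ny, nz).
    K_true : number of planted contiguous parcels.
    T : number of time points.
    snr : ratio of latent-signal s.d. to noise s.d. (both Gaussian).
    mask_kind : 'box' (full grid) or 'ellipsoid' (inscribed).
    seed : RNG seed; fixes mask seeds, latents and noise.
    """

    shape: tuple[int, int, int] = (20, 20, 12)
    K_true: int = 8
    T: int = 60
    snr: float = 8.0
    mask_kind: str = "box"
    seed: int = 0
    smooth_window: int = 1  # >1 applies a moving-average to the latents

    def __post_init__(self) -> None:
        if self.K_true < 1:
            raise ValueError("K_true >= 1 required")
        if self.T < 2:
            raise ValueError("T >= 2 required")
        if not self.snr > 0:
            raise ValueError("snr > 0 required")
        if self.mask_kind not in ("box", "ellipsoid"):
            raise ValueError("mask_kind must be 'box' or 'ellipsoid'")


def _make_mask(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.shape
    if spec.mask_kind == "box":
        return np.ones(spec.shape, dtype=bool)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    x, y, z = np.ogrid[:nx, :ny, :nz]
    r = ((x - cx) / (nx / 2)) ** 2 + ((y - cy) / (ny / 2)) ** 2 + ((z - cz) / (nz / 2)) ** 2
    mask = r <= 1.0
    if not mask.any():
        raise ValueError("degenerate mask: ellipsoid contains no voxels")
    return mask


def make_phantom(spec: PhantomSpec) -> tuple[BoldVolume, BrainMask, Atlas]:
    """Generate (volume, mask, ground-truth atlas) from a :class:`PhantomSpec`.

    Parcels are grown by nearest-seed assignment in voxel-index Euclidean
    distance from ``K_true`` random in-mask seed voxels (ties broken toward
    the lower parcel id), which yields irregular but contiguous regions.
    """
    rng = np.random.default_rng(spec.seed)
    mask = BrainMask(data=_make_mask(spec))
    coords = mask_coords(mask)
    n0 = coords.shape[0]
    if spec.K_true > n0:
        raise ValueError(f"K_true = {spec.K_true} exceeds mask size N0 = {n0}")

    seed_idx = rng.choice(n0, size=spec.K_true, replace=False)
    seeds = coords[seed_idx].astype(float)
    # nearest-seed growth; cKDTree breaks exact ties toward the lower seed id
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    parcel = np.argmin(d2, axis=1) + 1  # argmin takes the first minimum: low id wins

    latents = rng.standard_normal((spec.K_true, spec.T))
    if spec.smooth_window > 1:
        kernel = np.ones(spec.smooth_window) / spec.smooth_window
        latents = np.apply_along_axis(
            lambda s: np.convolve(s, kernel, mode="same"), 1, latents
        )
        latents /= latents.std(axis=1, keepdims=True)
    noise = rng.standard_normal((n0, spec.T)) / spec.snr

    data = np.zeros(spec.shape + (spec.T,), dtype=float)
    data[coords[:, 0], coords[:, 1], coords[:, 2], :] = latents[parcel - 1] + noise

    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[coords[:, 0], coords[:, 1], coords[:, 2]] = parcel
    atlas = Atlas(labels=labels).densified()
    return BoldVolume(data=data), mask, atlas


def nearest_in_mask(points: np.ndarray, mask: BrainMask) -> np.ndarray:
    """Snap arbitrary voxel-space points to the nearest in-mask voxel."""
    coords = mask_coords(mask)
    _, idx = cKDTree(coords).query(np.atleast_2d(points))
    return coords[idx]


def permute_time_series(volume: BoldVolume, mask: BrainMask, seed: int = 0) -> BoldVolume:
    """Randomly reassign whole in-mask time courses to in-mask voxels.

    The multiset of voxel time courses is preserved exactly; only their
    spatial arrangement is destroyed. Out-of-mask voxels are untouched.
    """
    rng = np.random.default_rng(seed)
    coords = mask_coords(mask)
    series = volume.data[coords[:, 0], coords[:, 1], coords[:, 2], :]
    perm = rng.permutation(series.shape[0])
    out = volume.data.copy()
    out[coords[:, 0], coords[:, 1], coords[:, 2], :] = series[perm]
    return BoldVolume(data=out, affine=volume.affine)


def permute_weight_matrix(W, seed: int = 0) -> np.ndarray:
    """Uniformly permute the off-diagonal upper triangle of a square matrix.

    The result is symmetrized and the diagonal preserved, so the multiset of
    upper-triangle edge weights is conserved while their placement is random.
    Sparse inputs are densified (a random edge placement is dense anyway).
    """
    if sp.issparse(W):
        W = W.toarray()
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    rng = np.random.default_rng(seed)
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = W[iu, ju]
    vals = vals[rng.permutation(vals.size)]
    out = np.zeros_like(W)
    out[iu, ju] = vals
    out += out.T
    out[np.diag_indices(n)] = W[np.diag_indices(n)]
    return out


def connected_parcels(atlas: Atlas) -> bool:
    """True iff every atlas cluster is a single 26-connected component."""
    for lab in range(1, atlas.n_clusters + 1):
        _, n = ndimage.label(atlas.labels == lab, structure=STRUCT_26)
        if n != 1:
            return False
    return True
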