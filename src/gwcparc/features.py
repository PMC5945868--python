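"""Per-supervoxel features, their distance graphs, and spatial adjacency.

Three features (M = 3) describe each supervoxel:

1. mean intensity — the supervoxel's mean z-scored time course (d1 = T),
2. intensity histogram — a 12-bin normalized histogram of the temporal-mean
   image over the supervoxel's voxels,
3. LBP histogram — a 10-bin normalized histogram of rotation-invariant
   6-neighbor local binary pattern classes on the temporal-mean image.

The 6-neighbor LBP thresholds each face neighbor against the center voxel
(ties encode 1; out-of-mask neighbors encode 0), giving 2^6 = 64 binary
patterns. Patterns are grouped into their orbits under the 24 proper
rotations of the cube acting on the six face directions; Burnside's lemma
gives exactly 10 orbits, hence 10 histogram bins.

Everything downstream consumes these features only through pairwise
Euclidean distance graphs, each normalized by its own maximum entry so that
heterogeneous feature scales are commensurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations, product

import numpy as np

from .io import BoldVolume, BrainMask, mask_coords
from .supervoxels import SupervoxelMap, zscore_series

__all__ = [
    "FeatureSet",
    "DistanceGraph",
    "SpatialAdjacency",
    "mean_intensity_feature",
    "intensity_histogram_feature",
    "lbp3d_codes",
    "lbp_histogram_feature",
    "distance_graph",
    "normalize_graph",
    "spatial_adjacency",
    "default_feature_set",
    "lbp_group_table",
]


@dataclass
class FeatureSet:
    """The M feature matrices Y^(m), each d_m x N over the same supervoxels."""

    Y: list
    names: list

    def __post_init__(self) -> None:
        if len(self.Y) < 1:
            raise ValueError("at least one feature required")
        ns = {y.shape[1] for y in self.Y}
        if len(ns) != 1:
            raise ValueError("feature matrices disagree on supervoxel count")

    @property
    def M(self) -> int:
        return len(self.Y)

    @property
    def d(self) -> list:
        return [y.shape[0] for y in self.Y]


@dataclass
class DistanceGraph:
    """A symmetric nonnegative N x N pairwise-distance graph."""

    G: np.ndarray
    normalized: bool = False


@dataclass
class SpatialAdjacency:
    """Binary supervoxel adjacency S0 and the sparsity estimate k."""

    S0: np.ndarray
    k_est: int


def mean_intensity_feature(sv: SupervoxelMap) -> np.ndarray:
    """T x N matrix of mean z-scored time courses (already held by the map)."""
    return np.asarray(sv.mean_series, dtype=float)


def temporal_mean_image(volume: BoldVolume) -> np.ndarray:
    return volume.data.mean(axis=3)


def intensity_histogram_feature(
    volume3d: np.ndarray, sv: SupervoxelMap, n_bins: int = 12
) -> np.ndarray:
    """Per-supervoxel intensity histogram over equal-width global bins.

    Bins span the in-mask intensity range of ``volume3d``; each column is
    normalized to sum to 1. A constant image degenerates to one-hot columns.
    """
    inmask = sv.labels > 0
    vals = volume3d[inmask]
    lab = sv.labels[inmask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:  # constant image: all mass in one bin
        out = np.zeros((n_bins, sv.n))
        out[0, :] = 1.0
        return out
    edges = np.linspace(lo, hi, n_bins + 1)
    binned = np.clip(np.digitize(vals, edges[1:-1]), 0, n_bins - 1)
    out = np.zeros((n_bins, sv.n))
    np.add.at(out, (binned, lab - 1), 1.0)
    return out / out.sum(axis=0, keepdims=True)


# --- 6-neighbor rotation-invariant LBP --------------------------------------

_DIRS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=int,
)


def _cube_rotations():
    mats = []
    for perm in permutations(range(3)):
        for signs in product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=int)
            for row, (p, s) in enumerate(zip(perm, signs)):
                m[row, p] = s
            if round(np.linalg.det(m)) == 1:
                mats.append(m)
    assert len(mats) == 24
    return mats


@lru_cache(maxsize=1)
def lbp_group_table() -> np.ndarray:
    """Map each of the 64 face-neighbor patterns to its rotation-orbit class.

    Classes are indexed 0..9 in ascending order of each orbit's minimal
    pattern integer.
    """
    dir_index = {tuple(d): i for i, d in enumerate(_DIRS)}
    perms = []
    for m in _cube_rotations():
        perms.append([dir_index[tuple(m @ d)] for d in _DIRS])
    canon = np.empty(64, dtype=np.int64)
    for pat in range(64):
        bits = [(pat >> i) & 1 for i in range(6)]
        images = []
        for perm in perms:
            images.append(sum(bits[i] << perm[i] for i in range(6)))
        canon[pat] = min(images)
    reps = np.unique(canon)
    lut = np.zeros(64, dtype=np.int64)
    for cls, rep in enumerate(np.sort(reps)):
        lut[canon == rep] = cls
    return lut


def lbp3d_codes(volume3d: np.ndarray, mask: BrainMask) -> np.ndarray:
    """Per-voxel LBP class id (0..9) inside the mask, -1 outside.

    Each face neighbor contributes a bit: 1 if neighbor >= center, else 0.
    Out-of-mask (and out-of-grid) neighbors count as below center.
    """
    vol = np.asarray(volume3d, dtype=float)
    inm = mask.data
    pattern = np.zeros(vol.shape, dtype=np.int64)
    masked = np.where(inm, vol, -np.inf)
    for bit, d in enumerate(_DIRS):
        # shifted[x] holds the neighbor value at x + d (or -inf past the edge)
        shifted = np.full(vol.shape, -np.inf)
        dst = tuple(slice(max(-d[a], 0), vol.shape[a] - max(d[a], 0)) for a in range(3))
        src = tuple(slice(max(d[a], 0), vol.shape[a] + min(d[a], 0)) for a in range(3))
        shifted[dst] = masked[src]
        pattern |= (shifted >= vol).astype(np.int64) << bit
    codes = lbp_group_table()[pattern]
    codes[~inm] = -1
    return codes


def lbp_histogram_feature(codes: np.ndarray, sv: SupervoxelMap) -> np.ndarray:
    """10 x N normalized histogram of LBP classes per supervoxel."""
    inmask = sv.labels > 0
    c = codes[inmask]
    lab = sv.labels[inmask]
    if (c < 0).any():
        raise ValueError("codes and supervoxel map disagree on the mask")
    out = np.zeros((10, sv.n))
    np.add.at(out, (c, lab - 1), 1.0)
    return out / out.sum(axis=0, keepdims=True)


# --- distance graphs ---------------------------------------------------------

def distance_graph(points: np.ndarray) -> DistanceGraph:
    """Pairwise Euclidean distances between the columns of a d x N matrix."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError("need a d x N matrix with N >= 2")
    sq = (pts * pts).sum(axis=0)
    g2 = sq[:, None] + sq[None, :] - 2.0 * (pts.T @ pts)
    np.maximum(g2, 0.0, out=g2)
    g = np.sqrt(g2)
    np.fill_diagonal(g, 0.0)
    return DistanceGraph(G=0.5 * (g + g.T), normalized=False)


def normalize_graph(graph: DistanceGraph) -> DistanceGraph:
    """Divide every entry by the graph's maximum (no-op for an all-zero graph)."""
    mx = float(graph.G.max())
    G = graph.G if mx <= 0 else graph.G / mx
    return DistanceGraph(G=G, normalized=True)


def spatial_adjacency(sv: SupervoxelMap) -> SpatialAdjacency:
    """Supervoxel adjacency under voxel-level 26-connectivity, plus k.

    S0[i, j] = 1 iff some voxel of supervoxel i touches some voxel of
    supervoxel j within the 26-neighborhood. k is the rounded (half-to-even)
    mean column sum of S0 — the average neighbor count.
    """
    n = sv.n
    if n < 2:
        raise ValueError("graph too small: need at least 2 supervoxels")
    lab = sv.labels
    S0 = np.zeros((n, n), dtype=np.int8)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ]
    shape = lab.shape
    for d in offsets:
        src = tuple(slice(max(-d[a], 0), shape[a] - max(d[a], 0)) for a in range(3))
        dst = tuple(slice(max(d[a], 0), shape[a] + min(d[a], 0)) for a in range(3))
        a = lab[src].ravel()
        b = lab[dst].ravel()
        ok = (a > 0) & (b > 0) & (a != b)
        S0[a[ok] - 1, b[ok] - 1] = 1
        S0[b[ok] - 1, a[ok] - 1] = 1
    k_est = int(round(float(S0.sum(axis=0).mean())))
    return SpatialAdjacency(S0=S0, k_est=k_est)


def default_feature_set(volume: BoldVolume, mask: BrainMask, sv: SupervoxelMap) -> FeatureSet:
    """The standard M = 3 feature set used by the parcellation pipeline."""
    mean3d = temporal_mean_image(volume)
    return FeatureSet(
        Y=[
            mean_intensity_feature(sv),
            intensity_histogram_feature(mean3d, sv),
            lbp_histogram_feature(lbp3d_codes(mean3d, mask), sv),
        ],
        names=["mean_intensity", "intensity_histogram", "lbp_histogram"],
    )
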