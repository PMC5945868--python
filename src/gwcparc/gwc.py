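"""Graph-without-cut: joint affinity-graph learning and parcellation.

Given N supervoxels with centroid coordinates X and M feature matrices
Y^(m), the method learns a column-simplex, k-sparse affinity graph S whose
Laplacian has exactly K zero eigenvalues — i.e., S has exactly K connected
components — by minimizing

    sum_ij ||x_i - x_j||^2 s_ij
  + lambda sum_m alpha_m sum_ij ||y_i^(m) - y_j^(m)||^2 s_ij
  + mu sum_ij ||z_i - z_j||^2 s_ij
  + beta ||S||_F^2 + beta gamma ||alpha||^2

subject to column-simplex constraints on S, a simplex constraint on the
feature weights alpha, and Z'Z = I with Z an N x K spectral embedding.
All pairwise-distance terms enter as max-normalized graphs, squared.

Block-coordinate updates, each optimal for its subproblem:

* Z — the K eigenvectors of the K smallest eigenvalues of the Laplacian of
  (S + S')/2;
* S — one k-sparse simplex QP per column of the cost matrix P (squared
  normalized graphs, weighted sum);
* alpha — a simplex projection of -lambda q / (2 beta_bar gamma), where
  q_m is the Hadamard contraction of S with the m-th squared feature graph
  and beta_bar is the mean of the per-column betas from the S-update.

Because mu is large (1e4 by default), rows of Z collapse within nascent
components and the mu-term forces cross-component affinities out of each
column's k cheapest costs, pinching S into exactly K components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from . import qp
from .features import (
    DistanceGraph,
    FeatureSet,
    default_feature_set,
    distance_graph,
    normalize_graph,
    spatial_adjacency,
)
from .io import Atlas, BoldVolume, BrainMask
from .spectral import spectral_cluster
from .supervoxels import SlicParams, SupervoxelMap, run_slic

logger = logging.getLogger(__name__)

__all__ = [
    "GwcParams",
    "AffinityGraph",
    "SpectralEmbedding",
    "IterationRecord",
    "compute_P",
    "update_Z",
    "update_S",
    "compute_q",
    "update_alpha",
    "fit",
    "extract_labels",
    "map_to_voxels",
    "parcellate",
]

# Affinities below this do not count as graph edges when counting connected
# components. Columns of S sum to 1 over <= k nonzeros, so genuine affinities
# are ~1/k (order 1e-1). In exact arithmetic the rank mechanism drives
# cross-component entries to 0; in floating point, near-tied costs leave
# residues of order (cost spread)/(k * mu) ~ 1e-8..1e-6, several orders below
# any real edge. 1e-4 (0.01% of a column's mass) cleanly separates the two.
_EDGE_EPS = 1e-4


@dataclass
class GwcParams:
    """Tuning parameters of the graph learner.

    K is the initialized cluster number; lambda_ (0.1) weighs the feature
    terms against the spatial term; gamma (1) regularizes the feature
    weights; mu (1e4) enforces the K-component constraint; k is the column
    sparsity of S (estimated from supervoxel adjacency when None).
    """

    K: int = 100
    lambda_: float = 0.1
    gamma: float = 1.0
    mu: float = 1e4
    k: int | None = None
    max_iter: int = 100
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K >= 2 required")
        if min(self.lambda_, self.gamma, self.mu) <= 0:
            raise ValueError("lambda_, gamma, mu must be positive")
        if self.k is not None and self.k < 1:
            raise ValueError("k >= 1 required")


@dataclass
class AffinityGraph:
    """The learned graph S (columns on the simplex, <= k nonzeros each)."""

    S: np.ndarray
    beta_bar: float

    def components(self) -> tuple[int, np.ndarray]:
        s_sym = 0.5 * (self.S + self.S.T)
        return connected_components(sp.csr_matrix(s_sym > _EDGE_EPS), directed=False)


@dataclass
class SpectralEmbedding:
    Z: np.ndarray
    eigvals: np.ndarray


@dataclass
class IterationRecord:
    iteration: int
    objective: float
    alpha: np.ndarray
    n_components: int
    s_change: float
    beta_bar: float


def compute_P(
    Gx: DistanceGraph,
    Gy: list[DistanceGraph],
    Gz: DistanceGraph | None,
    alpha: np.ndarray,
    params: GwcParams,
) -> np.ndarray:
    """Cost matrix P: weighted sum of the squared normalized graphs."""
    graphs = [Gx] + list(Gy) + ([Gz] if Gz is not None else [])
    n = Gx.G.shape[0]
    for g in graphs:
        if not g.normalized:
            raise ValueError("all graphs entering P must be max-normalized")
        if g.G.shape != (n, n):
            raise ValueError("graph dimension mismatch")
    P = Gx.G * Gx.G
    for a_m, g in zip(alpha, Gy):
        P = P + params.lambda_ * a_m * (g.G * g.G)
    if Gz is not None:
        P = P + params.mu * (Gz.G * Gz.G)
    return P


def update_Z(S: np.ndarray | AffinityGraph, K: int) -> SpectralEmbedding:
    """Eigenvectors of the K smallest Laplacian eigenvalues of (S + S')/2."""
    Smat = S.S if isinstance(S, AffinityGraph) else np.asarray(S, float)
    n = Smat.shape[0]
    if K > n:
        raise ValueError("K cannot exceed the number of supervoxels")
    s_sym = 0.5 * (Smat + Smat.T)
    L = np.diag(s_sym.sum(axis=1)) - s_sym
    w, v = scipy.linalg.eigh(L)
    return SpectralEmbedding(Z=v[:, :K], eigvals=w[:K])


def update_S(P: np.ndarray, k: int) -> AffinityGraph:
    """Solve the per-column k-sparse simplex QP; average the implied betas."""
    n = P.shape[0]
    S = np.zeros((n, n))
    betas = []
    for i in range(n):
        sol = qp.sparse_simplex_update(P[:, i], k, exclude=i)
        S[:, i] = sol.s
        if sol.beta is not None and sol.beta > 0:
            betas.append(sol.beta)
    beta_bar = float(np.mean(betas)) if betas else 0.0
    return AffinityGraph(S=S, beta_bar=beta_bar)


def compute_q(Gy: list[DistanceGraph], S: np.ndarray | AffinityGraph) -> np.ndarray:
    """q_m = <squared m-th feature graph, S> (Hadamard contraction)."""
    Smat = S.S if isinstance(S, AffinityGraph) else np.asarray(S, float)
    return np.array([float(((g.G * g.G) * Smat).sum()) for g in Gy])


def update_alpha(
    q: np.ndarray, beta_bar: float, params: GwcParams, prev_alpha: np.ndarray
) -> np.ndarray:
    """Simplex projection of -lambda q / (2 beta_bar gamma)."""
    if beta_bar <= 0:
        warnings.warn("degenerate beta_bar <= 0; keeping previous alpha")
        return prev_alpha
    return qp.project_simplex(-params.lambda_ * q / (2.0 * beta_bar * params.gamma)).s


def fit(
    sv: SupervoxelMap,
    features: FeatureSet,
    params: GwcParams,
) -> tuple[AffinityGraph, list[IterationRecord]]:
    """Alternating optimization until S converges (relative Frobenius change).

    alpha starts uniform at 1/M; S is initialized from the cost matrix
    without the mu-term (no Z yet); then Z, S, alpha are updated in turn.
    """
    n = sv.n
    if any(y.shape[1] != n for y in features.Y):
        raise ValueError("feature matrices do not match the supervoxel count")
    k = params.k if params.k is not None else spatial_adjacency(sv).k_est
    k = int(np.clip(k, 1, n - 2))
    M = features.M
    alpha = np.full(M, 1.0 / M)

    Gx = normalize_graph(distance_graph(sv.centroids))
    Gy = [normalize_graph(distance_graph(Y)) for Y in features.Y]

    P0 = compute_P(Gx, Gy, None, alpha, params)
    graph = update_S(P0, k)
    history: list[IterationRecord] = []

    for it in range(1, params.max_iter + 1):
        emb = update_Z(graph, params.K)
        Gz = normalize_graph(distance_graph(emb.Z.T))
        P = compute_P(Gx, Gy, Gz, alpha, params)
        new_graph = update_S(P, k)
        alpha = update_alpha(compute_q(Gy, new_graph), new_graph.beta_bar, params, alpha)

        change = float(
            np.linalg.norm(new_graph.S - graph.S)
            / max(1.0, np.linalg.norm(graph.S))
        )
        objective = float(
            (P * new_graph.S).sum()
            + new_graph.beta_bar
            * (np.linalg.norm(new_graph.S) ** 2 + params.gamma * alpha @ alpha)
        )
        if not np.isfinite(objective):
            raise FloatingPointError(f"non-finite objective at iteration {it}")
        ncomp, _ = new_graph.components()
        history.append(
            IterationRecord(
                iteration=it,
                objective=objective,
                alpha=alpha.copy(),
                n_components=int(ncomp),
                s_change=change,
                beta_bar=new_graph.beta_bar,
            )
        )
        logger.debug(
            "iter %d: obj=%.6g change=%.3g components=%d", it, objective, change, ncomp
        )
        graph = new_graph
        if change < params.tol:
            break
    return graph, history


def extract_labels(S: AffinityGraph, K: int, seed: int = 0) -> np.ndarray:
    """Cluster labels (1..K_actual) for the supervoxels from the learned graph.

    If (S + S')/2 has exactly K connected components they are the clusters;
    otherwise normalized-cut spectral clustering with K clusters is applied
    to the symmetrized graph.
    """
    ncomp, comp = S.components()
    if ncomp == K:
        labels = comp + 1
    else:
        logger.info("graph has %d components (K = %d); applying Ncut", ncomp, K)
        labels = spectral_cluster(0.5 * (S.S + S.S.T), K, seed=seed)
    uniq = np.unique(labels)
    lut = np.zeros(int(uniq.max()) + 1, dtype=np.int64)
    lut[uniq] = np.arange(1, uniq.size + 1)
    return lut[labels]


def map_to_voxels(sv_labels: np.ndarray, sv: SupervoxelMap, mask: BrainMask,
                  affine=None) -> Atlas:
    """Lift supervoxel cluster labels to the voxel grid."""
    sv_labels = np.asarray(sv_labels)
    if sv_labels.shape[0] != sv.n:
        raise ValueError("need one label per supervoxel")
    out = np.zeros(sv.labels.shape, dtype=np.int64)
    inm = sv.labels > 0
    if not np.array_equal(inm, mask.data):
        raise ValueError("supervoxel map and mask disagree")
    out[inm] = sv_labels[sv.labels[inm] - 1]
    return Atlas(labels=out, affine=np.eye(4) if affine is None else affine).densified()


def parcellate(
    volume: BoldVolume,
    mask: BrainMask,
    slic_params: SlicParams | None = None,
    gwc_params: GwcParams | None = None,
) -> tuple[Atlas, dict]:
    """Full pipeline: supervoxels -> features -> graph learning -> atlas.

    Returns the atlas and a run report (alpha/objective trajectories,
    component counts, K_actual).
    """
    slic_params = slic_params or SlicParams()
    gwc_params = gwc_params or GwcParams()
    sv = run_slic(volume, mask, slic_params)
    feats = default_feature_set(volume, mask, sv)
    graph, history = fit(sv, feats, gwc_params)
    sv_labels = extract_labels(graph, gwc_params.K, seed=gwc_params.seed)
    atlas = map_to_voxels(sv_labels, sv, mask, affine=volume.affine)
    report = {
        "n_supervoxels": int(sv.n),
        "k_used": int(gwc_params.k) if gwc_params.k is not None
        else int(spatial_adjacency(sv).k_est),
        "K_init": int(gwc_params.K),
        "K_actual": int(atlas.n_clusters),
        "n_iterations": len(history),
        "alpha": [rec.alpha.tolist() for rec in history],
        "objective": [rec.objective for rec in history],
        "n_components": [rec.n_components for rec in history],
        "s_change": [rec.s_change for rec in history],
    }
    return atlas, report
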