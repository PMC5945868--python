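"""Normalized-cut spectral clustering engine shared by the pipeline and baselines.

Given a symmetric nonnegative affinity matrix W (dense or sparse), embed the
nodes with the top-K eigenvectors of the symmetrically normalized affinity
D^{-1/2} W D^{-1/2}, row-normalize, and discretize with seeded k-means.
Disconnected affinity graphs are handled by allocating the K clusters to the
connected components proportionally to their sizes and clustering each
component independently.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

__all__ = ["spectral_cluster"]


def _embed_and_discretize(W, K: int, seed: int) -> np.ndarray:
    n = W.shape[0]
    if K >= n:
        return np.arange(n)
    if sp.issparse(W):
        W = W.tocsr()
        d = np.asarray(W.sum(axis=1)).ravel()
    else:
        d = W.sum(axis=1)
    d_isqrt = np.where(d > 0, 1.0 / np.sqrt(np.maximum(d, 1e-300)), 0.0)
    if sp.issparse(W):
        Dm = sp.diags(d_isqrt)
        A = Dm @ W @ Dm
    else:
        A = W * d_isqrt[:, None] * d_isqrt[None, :]
    # deterministic Lanczos start vector; dense path for small problems
    if n <= 200:
        Ad = A.toarray() if sp.issparse(A) else A
        w, v = np.linalg.eigh(0.5 * (Ad + Ad.T))
        emb = v[:, np.argsort(w)[::-1][:K]]
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        w, v = sp.linalg.eigsh(A, k=K, which="LA", v0=v0)
        emb = v[:, np.argsort(w)[::-1]]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    return km.fit_predict(emb)


def spectral_cluster(W, K: int, seed: int = 0) -> np.ndarray:
    """Partition the nodes of affinity W into K clusters; labels 1..K_actual.

    Negative affinities are clipped to zero before embedding (the
    eigen-embedding requires nonnegative weights).
    """
    if sp.issparse(W):
        W = W.tocsr()
        W.data = np.maximum(W.data, 0.0)
        W.eliminate_zeros()
        struct = W
    else:
        W = np.maximum(np.asarray(W, dtype=float), 0.0)
        struct = sp.csr_matrix(W)
    n = W.shape[0]
    if K < 1:
        raise ValueError("K >= 1 required")
    ncomp, comp = connected_components(struct, directed=False)
    labels = np.zeros(n, dtype=np.int64)
    if ncomp == 1:
        labels = _embed_and_discretize(W, K, seed) + 1
    elif ncomp >= K:
        # more components than clusters: the K-1 largest stand alone, the
        # rest pool into one catch-all cluster
        sizes = np.bincount(comp)
        big = np.argsort(sizes)[::-1][: K - 1]
        labels[:] = K
        for rank, c in enumerate(big):
            labels[comp == c] = rank + 1
    else:
        sizes = np.bincount(comp).astype(float)
        alloc = np.maximum(1, np.floor(K * sizes / sizes.sum()).astype(int))
        # largest-remainder correction so the allocations sum to K
        while alloc.sum() > K:
            alloc[np.argmax(alloc)] -= 1
        while alloc.sum() < K:
            rem = K * sizes / sizes.sum() - alloc
            alloc[np.argmax(rem)] += 1
        nxt = 1
        for c in range(ncomp):
            idx = np.nonzero(comp == c)[0]
            sub = W[np.ix_(idx, idx)] if not sp.issparse(W) else W[idx][:, idx]
            if alloc[c] == 1 or idx.size <= alloc[c]:
                sub_labels = (
                    np.zeros(idx.size, dtype=np.int64)
                    if alloc[c] == 1
                    else np.arange(idx.size) % alloc[c]
                )
            else:
                sub_labels = _embed_and_discretize(sub, int(alloc[c]), seed)
            labels[idx] = sub_labels + nxt
            nxt += int(sub_labels.max()) + 1
    # densify to 1..K_actual
    uniq = np.unique(labels)
    lut = np.zeros(int(uniq.max()) + 1, dtype=np.int64)
    lut[uniq] = np.arange(1, uniq.size + 1)
    return lut[labels]
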