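import numpy as np
import pytest
import scipy.linalg

import gwcparc as g
from gwcparc.features import DistanceGraph, FeatureSet, distance_graph, normalize_graph
from gwcparc.gwc import (
    AffinityGraph,
    GwcParams,
    compute_P,
    compute_q,
    extract_labels,
    fit,
    map_to_voxels,
    update_S,
    update_Z,
    update_alpha,
)
from gwcparc.io import BrainMask
from gwcparc.qp import sparse_simplex_update
from tests.test_qp import slsqp_project


def _norm_graph(rng, n):
    return normalize_graph(distance_graph(rng.standard_normal((3, n))))


def test_compute_p_matches_double_loop(rng):
    n = 4
    Gx = _norm_graph(rng, n)
    Gy = [_norm_graph(rng, n) for _ in range(2)]
    Gz = _norm_graph(rng, n)
    alpha = np.array([0.3, 0.7])
    params = GwcParams(K=2, lambda_=0.1, mu=1e4)
    P = compute_P(Gx, Gy, Gz, alpha, params)
    for i in range(n):
        for j in range(n):
            expected = Gx.G[i, j] ** 2
            expected += 0.1 * sum(a * gm.G[i, j] ** 2 for a, gm in zip(alpha, Gy))
            expected += 1e4 * Gz.G[i, j] ** 2
            assert P[i, j] == pytest.approx(expected, rel=1e-12)


def test_compute_p_one_hot_alpha_isolates_feature(rng):
    n = 5
    Gx = _norm_graph(rng, n)
    Gy = [_norm_graph(rng, n) for _ in range(3)]
    params = GwcParams(K=2, lambda_=0.5)
    P = compute_P(Gx, Gy, None, np.array([0.0, 1.0, 0.0]), params)
    np.testing.assert_allclose(P, Gx.G**2 + 0.5 * Gy[1].G**2)


def test_compute_p_rejects_unnormalized(rng):
    Gx = distance_graph(rng.standard_normal((3, 4)))
    with pytest.raises(ValueError, match="normalized"):
        compute_P(Gx, [], None, np.array([]), GwcParams(K=2))


def test_update_z_block_diagonal_null_space():
    S = np.zeros((6, 6))
    for blk in ([0, 1], [2, 3], [4, 5]):
        for i in blk:
            for j in blk:
                if i != j:
                    S[i, j] = 0.5
    emb = update_Z(S, K=3)
    np.testing.assert_allclose(emb.eigvals, 0.0, atol=1e-10)
    s_sym = 0.5 * (S + S.T)
    L = np.diag(s_sym.sum(1)) - s_sym
    assert np.trace(emb.Z.T @ L @ emb.Z) == pytest.approx(0.0, abs=1e-10)


def test_update_z_complete_basis_trace():
    rng = np.random.default_rng(3)
    S = np.abs(rng.standard_normal((5, 5)))
    emb = update_Z(S, K=5)
    s_sym = 0.5 * (S + S.T)
    L = np.diag(s_sym.sum(1)) - s_sym
    assert np.trace(emb.Z.T @ L @ emb.Z) == pytest.approx(np.trace(L))


def test_update_z_matches_dense_eigensolver_oracle(rng):
    for n, K in [(8, 3), (12, 5)]:
        S = np.abs(rng.standard_normal((n, n))) * (rng.random((n, n)) < 0.4)
        emb = update_Z(S, K=K)
        s_sym = 0.5 * (S + S.T)
        L = np.diag(s_sym.sum(1)) - s_sym
        w = np.linalg.eigvalsh(L)  # independent dense oracle
        got = np.trace(emb.Z.T @ L @ emb.Z)
        assert got == pytest.approx(np.sort(w)[:K].sum(), abs=1e-8)
        np.testing.assert_allclose(emb.Z.T @ emb.Z, np.eye(K), atol=1e-8)


def test_update_s_tie_case_uniform():
    n, k = 5, 2
    P = np.full((n, n), 100.0)
    np.fill_diagonal(P, 0.0)
    P[1, 0] = P[2, 0] = 0.0  # two zero off-diagonal costs in column 0
    graph = update_S(P, k)
    np.testing.assert_allclose(graph.S[[1, 2], 0], 0.5)
    assert (graph.S[:, 0] > 0).sum() == 2


def test_update_s_sparsity_and_column_objective(rng):
    n, k = 8, 3
    P = np.abs(rng.standard_normal((n, n)))
    P = 0.5 * (P + P.T)
    np.fill_diagonal(P, 0.0)
    graph = update_S(P, k)
    for i in range(n):
        col = graph.S[:, i]
        assert (col > 0).sum() <= k
        assert col[i] == 0.0
        assert col.sum() == pytest.approx(1.0, abs=1e-10)
        # column solution must match the standalone QP
        sol = sparse_simplex_update(P[:, i], k, exclude=i)
        np.testing.assert_allclose(col, sol.s, atol=1e-12)


def test_compute_q_cases(rng):
    n = 4
    Gy = [_norm_graph(rng, n) for _ in range(3)]
    assert np.allclose(compute_q(Gy, np.zeros((n, n))), 0.0)
    S = np.abs(rng.standard_normal((n, n)))
    q = compute_q(Gy, S)
    for m, gm in enumerate(Gy):
        expected = sum(
            gm.G[i, j] ** 2 * S[i, j] for i in range(n) for j in range(n)
        )
        assert q[m] == pytest.approx(expected, rel=1e-10)
    same = [Gy[0], Gy[0]]
    q2 = compute_q(same, S)
    assert q2[0] == pytest.approx(q2[1])


def test_update_alpha_uniform_and_single():
    params = GwcParams(K=2, lambda_=0.1, gamma=1.0)
    a = update_alpha(np.full(3, 2.0), 0.5, params, np.full(3, 1 / 3))
    np.testing.assert_allclose(a, 1 / 3)
    a1 = update_alpha(np.array([7.0]), 0.5, params, np.array([1.0]))
    np.testing.assert_allclose(a1, [1.0])


def test_update_alpha_matches_qp_oracle():
    params = GwcParams(K=2, lambda_=0.1, gamma=1.0)
    q, beta_bar = np.array([1.0, 2.0, 4.0]), 0.05
    mine = update_alpha(q, beta_bar, params, np.full(3, 1 / 3))
    oracle = slsqp_project(-params.lambda_ * q / (2 * beta_bar * params.gamma))
    np.testing.assert_allclose(mine, oracle, atol=1e-6)


def test_update_alpha_degenerate_beta_keeps_previous():
    params = GwcParams(K=2)
    prev = np.array([0.2, 0.8])
    with pytest.warns(UserWarning, match="beta_bar"):
        out = update_alpha(np.ones(2), 0.0, params, prev)
    np.testing.assert_array_equal(out, prev)


@pytest.fixture(scope="module")
def fitted(small_phantom_module):
    vol, mask, truth = small_phantom_module
    sv = g.run_slic(vol, mask, g.SlicParams(n_supervoxels=40, m=10, seed=0))
    feats = g.default_feature_set(vol, mask, sv)
    graph, history = fit(sv, feats, GwcParams(K=4, k=9, seed=0))
    return sv, feats, graph, history


@pytest.fixture(scope="module")
def small_phantom_module():
    return g.make_phantom(g.PhantomSpec(shape=(12, 12, 8), K_true=4, T=40, snr=8.0, seed=1))


def test_fit_reaches_k_components(fitted):
    _, _, graph, history = fitted
    ncomp, _ = graph.components()
    assert ncomp == 4
    assert history[-1].n_components == 4


def test_fit_single_feature_alpha_stays_one(small_phantom_module):
    vol, mask, _ = small_phantom_module
    sv = g.run_slic(vol, mask, g.SlicParams(n_supervoxels=40, m=10, seed=0))
    feats = FeatureSet(Y=[sv.mean_series], names=["mean_intensity"])
    _, history = fit(sv, feats, GwcParams(K=4, k=9, max_iter=5))
    for rec in history:
        np.testing.assert_allclose(rec.alpha, [1.0])


def test_fit_deterministic(small_phantom_module):
    vol, mask, _ = small_phantom_module
    sv = g.run_slic(vol, mask, g.SlicParams(n_supervoxels=40, m=10, seed=0))
    feats = g.default_feature_set(vol, mask, sv)
    g1, h1 = fit(sv, feats, GwcParams(K=4, k=9, max_iter=5))
    g2, h2 = fit(sv, feats, GwcParams(K=4, k=9, max_iter=5))
    np.testing.assert_array_equal(g1.S, g2.S)
    for a, b in zip(h1, h2):
        assert a.objective == b.objective
        np.testing.assert_array_equal(a.alpha, b.alpha)


def test_block_updates_are_optimal(fitted, rng):
    """No random orthonormal Z / simplex column can beat the closed forms."""
    sv, feats, graph, _ = fitted
    s_sym = 0.5 * (graph.S + graph.S.T)
    L = np.diag(s_sym.sum(1)) - s_sym
    emb = update_Z(graph, K=4)
    best = np.trace(emb.Z.T @ L @ emb.Z)
    n = graph.S.shape[0]
    for _ in range(20):
        Q, _ = np.linalg.qr(rng.standard_normal((n, 4)))
        assert np.trace(Q.T @ L @ Q) >= best - 1e-8
    # adversarial S columns on a small cost matrix
    P = np.abs(rng.standard_normal((10, 10)))
    np.fill_diagonal(P, 0.0)
    k = 3
    for i in range(10):
        sol = sparse_simplex_update(P[:, i], k, exclude=i)
        if sol.beta is None or sol.beta <= 0:
            continue
        obj = P[:, i] @ sol.s + sol.beta * sol.s @ sol.s
        for _ in range(20):
            cand = rng.dirichlet(np.ones(9))
            s_rand = np.insert(cand, i, 0.0)
            assert P[:, i] @ s_rand + sol.beta * s_rand @ s_rand >= obj - 1e-9


def test_extract_labels_block_diagonal():
    S = np.zeros((6, 6))
    for blk in ([0, 1, 2], [3, 4, 5]):
        for i in blk:
            for j in blk:
                if i != j:
                    S[i, j] = 0.5
    labels = extract_labels(AffinityGraph(S=S, beta_bar=1.0), K=2)
    assert np.unique(labels).size == 2
    assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
    assert labels[0] != labels[3]


def test_extract_labels_splits_when_fewer_components():
    # one 6-node component with an obvious 2-block structure inside
    S = np.zeros((6, 6))
    for blk in ([0, 1, 2], [3, 4, 5]):
        for i in blk:
            for j in blk:
                if i != j:
                    S[i, j] = 1.0
    S[2, 3] = S[3, 2] = 0.05  # weak bridge: a single component
    labels = extract_labels(AffinityGraph(S=S, beta_bar=1.0), K=2, seed=0)
    assert np.unique(labels).size == 2
    assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1


def test_extract_labels_permutation_equivariant(rng):
    S = np.zeros((6, 6))
    for blk in ([0, 1, 2], [3, 4, 5]):
        for i in blk:
            for j in blk:
                if i != j:
                    S[i, j] = 0.7
    perm = rng.permutation(6)
    base = extract_labels(AffinityGraph(S=S, beta_bar=1.0), K=2)
    permuted = extract_labels(AffinityGraph(S=S[np.ix_(perm, perm)], beta_bar=1.0), K=2)
    # co-membership must be preserved under relabeling
    for i in range(6):
        for j in range(6):
            assert (base[perm[i]] == base[perm[j]]) == (permuted[i] == permuted[j])


def test_map_to_voxels_conservation(fitted, small_phantom_module):
    sv, _, graph, _ = fitted
    _, mask, _ = small_phantom_module
    labels = extract_labels(graph, K=4)
    atlas = map_to_voxels(labels, sv, mask)
    # voxel count of each cluster = sum of its member supervoxel sizes
    # (labels are densified order-preserving, so cluster c keeps its id)
    for c in np.unique(labels):
        assert (atlas.labels == c).sum() == sv.sizes[labels == c].sum()


def test_map_to_voxels_identity_and_constant(small_supervoxels, small_phantom):
    sv = small_supervoxels
    _, mask, _ = small_phantom
    const = map_to_voxels(np.ones(sv.n, dtype=int), sv, mask)
    assert const.n_clusters == 1
    assert (const.labels[mask.data] == 1).all()
    ident = map_to_voxels(np.arange(1, sv.n + 1), sv, mask)
    np.testing.assert_array_equal(ident.labels, sv.labels)
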