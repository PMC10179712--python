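"""GCN/GAT propagation, gated skips, pooling and graph encoding."""

import numpy as np
import pytest

from tridta.drug_graphs import AtomGraph, build_atom_graph
from tridta.gnn_encoder import (EncoderParams, GraphBatch, ShapeError, encode,
                                gat_attention, gat_layer, gated_skip,
                                gcn_layer)


def _dense_gcn(H, A, W):
    """Independent dense-matrix GCN: ReLU(D~^-1/2 A~ D~^-1/2 H W)."""
    At = A + np.eye(len(A))
    d = At.sum(axis=1)
    N = At / np.sqrt(np.outer(d, d))
    return np.maximum(N @ H @ W, 0.0)


def test_gcn_single_node_identity():
    x = np.array([[1.0, -2.0, 3.0]])
    out = gcn_layer(x, np.zeros((1, 1)), np.eye(3))
    assert np.allclose(out, np.maximum(x, 0.0))


def test_gcn_two_nodes_hand_computed():
    H = np.ones((2, 3))
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    out = gcn_layer(H, A, np.eye(3))
    # normalization matrix is [[.5,.5],[.5,.5]]: each row averages both
    assert np.allclose(out, np.ones((2, 3)))
    H2 = np.array([[1.0, 2.0, -1.0], [3.0, -4.0, 5.0]])
    assert np.allclose(gcn_layer(H2, A, np.eye(3)), _dense_gcn(H2, A, np.eye(3)))


def test_gcn_permutation_equivariance():
    rng = np.random.default_rng(0)
    n = 6
    A = (rng.random((n, n)) > 0.6).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    H = rng.normal(size=(n, 4))
    W = rng.normal(size=(4, 5))
    perm = rng.permutation(n)
    out = gcn_layer(H, A, W)
    out_p = gcn_layer(H[perm], A[np.ix_(perm, perm)], W)
    assert np.allclose(out_p, out[perm])


def test_gcn_edge_weights_matter():
    H = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    A1 = np.array([[0, 0.6, 0], [0.6, 0, 0.8], [0, 0.8, 0]])
    A2 = A1.copy()
    A2[0, 1] = A2[1, 0] = 1.2        # doubled weight changes propagation
    W = np.eye(2)
    assert not np.allclose(gcn_layer(H, A1, W), gcn_layer(H, A2, W))
    # all retained weights set to 1 recovers the unweighted update
    binary = (A1 > 0).astype(float)
    assert np.allclose(gcn_layer(H, binary, W),
                       _dense_gcn(H, binary, W))


def test_gat_rows_sum_to_one():
    rng = np.random.default_rng(1)
    n = 5
    A = np.zeros((n, n))
    for i, j in [(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)]:
        A[i, j] = A[j, i] = 1.0
    H = rng.normal(size=(n, 3))
    W = rng.normal(size=(3, 4))
    a = rng.normal(size=8)
    alpha = gat_attention(H, A, W, a)
    assert np.allclose(alpha.sum(axis=1), 1.0)


def test_gat_zero_attention_vector_is_uniform():
    rng = np.random.default_rng(2)
    n = 4
    A = np.array([[0, 1, 1, 0], [1, 0, 0, 0], [1, 0, 0, 1], [0, 0, 1, 0.0]])
    H = rng.normal(size=(n, 3))
    alpha = gat_attention(H, A, rng.normal(size=(3, 4)), np.zeros(8))
    for i in range(n):
        nbrs = int(A[i].sum()) + 1          # self-inclusive neighborhood
        row = alpha[i][alpha[i] > 0]
        assert len(row) == nbrs
        assert np.allclose(row, 1.0 / nbrs)


def test_gat_matches_brute_force_softmax_on_path_graph():
    """3-node path: attention recomputed independently, per neighborhood."""
    rng = np.random.default_rng(3)
    H = rng.normal(size=(3, 2))
    W = rng.normal(size=(2, 3))
    a = rng.normal(size=6)
    A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
    alpha = gat_attention(H, A, W, a)
    HW = H @ W
    for i in range(3):
        nbrs = [j for j in range(3) if A[i, j]] + [i]
        logits = []
        for j in nbrs:
            e = a[:3] @ HW[i] + a[3:] @ HW[j]   # center i, neighbor j
            logits.append(e if e > 0 else 0.2 * e)
        expect = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose([alpha[i, j] for j in nbrs], expect)
    out = gat_layer(H, A, W, a)
    assert out.shape == (3, 3)
    assert np.all(out >= 0)


def test_gat_isolated_node_no_nan():
    H = np.array([[1.0, 2.0], [3.0, 4.0]])
    A = np.zeros((2, 2))
    out = gat_layer(H, A, np.eye(2), np.ones(4))
    assert np.isfinite(out).all()


def test_gated_skip_zero_params_is_mean():
    rng = np.random.default_rng(4)
    Hn, Ho = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
    Z = np.zeros((3, 3))
    out = gated_skip(Hn, Ho, Z, Z, np.zeros(3))
    assert np.allclose(out, (Hn + Ho) / 2)


def test_gated_skip_saturates_to_new():
    rng = np.random.default_rng(5)
    Hn, Ho = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
    Z = np.zeros((2, 2))
    out = gated_skip(Hn, Ho, Z, Z, np.full(2, 50.0))
    assert np.allclose(out, Hn)


def test_gated_skip_elementwise_bounds():
    rng = np.random.default_rng(6)
    for _ in range(10):
        Hn, Ho = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        out = gated_skip(Hn, Ho, rng.normal(size=(4, 4)),
                         rng.normal(size=(4, 4)), rng.normal(size=4))
        assert np.all(out >= np.minimum(Hn, Ho) - 1e-12)
        assert np.all(out <= np.maximum(Hn, Ho) + 1e-12)


def _random_atom_graph(seed=0):
    return build_atom_graph("CC(C)Cc1ccc(cc1)C(C)C(=O)O")


def test_encode_output_shape_and_determinism():
    g = _random_atom_graph()
    params = EncoderParams(78, conv="gcn", rng=np.random.default_rng(0))
    z1 = encode(g, params)
    z2 = encode(g, params)
    assert z1.shape == (128,)
    assert np.array_equal(z1, z2)          # eval mode is bit-deterministic


@pytest.mark.parametrize("conv", ["gcn", "gat"])
@pytest.mark.parametrize("pooling", ["max", "mean"])
def test_encode_permutation_invariance(conv, pooling):
    g = _random_atom_graph()
    rng = np.random.default_rng(7)
    perm = rng.permutation(g.n_nodes)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(g.n_nodes)
    g_perm = AtomGraph(
        n_nodes=g.n_nodes,
        node_features=g.node_features[perm],
        edges=[(min(inv[i], inv[j]), max(inv[i], inv[j]))
               for i, j in g.edges],
        smiles=g.smiles)
    params = EncoderParams(78, conv=conv, pooling=pooling,
                           rng=np.random.default_rng(1))
    assert np.allclose(encode(g, params), encode(g_perm, params), atol=1e-8)


def test_skip_ablation_changes_output():
    g = _random_atom_graph()
    gated = EncoderParams(78, conv="gcn", use_gate=True,
                          rng=np.random.default_rng(2))
    ungated = EncoderParams(78, conv="gcn", use_gate=False,
                            rng=np.random.default_rng(2))
    assert not np.allclose(encode(g, gated), encode(g, ungated))


def test_empty_graph_rejected():
    g = AtomGraph(n_nodes=0, node_features=np.zeros((0, 78)), edges=[],
                  smiles="")
    params = EncoderParams(78, rng=np.random.default_rng(0))
    with pytest.raises(ShapeError):
        encode(g, params)


def test_feature_width_mismatch_rejected():
    g = _random_atom_graph()
    params = EncoderParams(33, rng=np.random.default_rng(0))
    with pytest.raises(ShapeError):
        encode(g, params)


def test_graph_batch_membership():
    g1 = build_atom_graph("CCO")
    g2 = build_atom_graph("c1ccccc1")
    batch = GraphBatch.from_graphs([g1, g2])
    assert batch.n_graphs == 2
    assert batch.n_nodes == g1.n_nodes + g2.n_nodes
    assert np.array_equal(np.bincount(batch.node_graph), [3, 6])
    # edge endpoints stay within their graph
    sides = batch.node_graph[batch.edge_src] == batch.node_graph[batch.edge_dst]
    assert sides.all()
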