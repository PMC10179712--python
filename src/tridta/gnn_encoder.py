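"""Graph encoders: three conv layers with gated skips, pooling, projection.

Any of the three graph types (atom, motif, weighted protein) is encoded
into a fixed 128-dimensional vector.  Layer widths follow the N -> 4N ->
4N -> 4N scheme, where N is the input feature width (78, 92 or 33).  The
first layer changes width and is ungated; layers two and three keep the
4N width and are fused with their input through a gated skip-connection

    z = sigmoid(H_new U1^T + H_old U2^T + b),  H = z*H_new + (1-z)*H_old,

an elementwise convex combination whose gate is learned per node and per
feature.  Graph-level readout is max or mean pooling over nodes, then two
fully-connected stages (4N -> 1024 -> 128) with dropout project to the
final embedding.

Convolution is either GCN with symmetric normalization over the
self-looped (optionally edge-weighted) adjacency, or single-head GAT with
softmax attention over neighborhoods that include the node itself (so
isolated nodes never face an empty softmax).  GAT ignores protein edge
weights: attention replaces them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import (Tensor, concat, gather, segment_max, segment_mean,
                        segment_sum, spmm)
from .drug_graphs import AtomGraph, MotifGraph
from .protein_graphs import WeightedProteinGraph

EMBEDDING_DIM = 128
LEAKY_SLOPE = 0.2


class ShapeError(ValueError):
    """Raised on inconsistent shapes between features and parameters."""


# ---------------------------------------------------------------------------
# batching

@dataclass
class GraphBatch:
    """Several graphs packed into one disjoint union.

    ``node_graph`` maps every node to its source graph; edges are stored
    once per direction (undirected input pairs are mirrored).
    """

    node_features: np.ndarray      # (N_total, F)
    edge_src: np.ndarray           # directed
    edge_dst: np.ndarray
    edge_weight: np.ndarray | None
    node_graph: np.ndarray         # (N_total,) graph membership
    n_graphs: int

    @classmethod
    def from_graphs(cls, graphs) -> "GraphBatch":
        feats, srcs, dsts, wts, members = [], [], [], [], []
        offset = 0
        weighted = False
        for g_idx, g in enumerate(graphs):
            if g.n_nodes == 0:
                raise ShapeError("cannot batch an empty graph")
            feats.append(np.asarray(g.node_features, dtype=float))
            members.append(np.full(g.n_nodes, g_idx, dtype=np.intp))
            cached = getattr(g, "_edge_cache", None)
            if cached is None:
                e = np.asarray(g.edges, dtype=np.intp).reshape(-1, 2)
                w = getattr(g, "edge_weights", None)
                w = (np.asarray(w, dtype=float) if w is not None
                     else np.ones(len(e)))
                cached = (e, w, getattr(g, "edge_weights", None) is not None)
                try:
                    g._edge_cache = cached
                except AttributeError:
                    pass
            e, w, has_w = cached
            srcs.append(e[:, 0] + offset)
            dsts.append(e[:, 1] + offset)
            wts.append(w)
            weighted = weighted or has_w
            offset += g.n_nodes
        src = np.concatenate(srcs)
        dst = np.concatenate(dsts)
        w = np.concatenate(wts)
        return cls(
            node_features=np.concatenate(feats, axis=0),
            edge_src=np.concatenate([src, dst]),   # mirror both directions
            edge_dst=np.concatenate([dst, src]),
            edge_weight=np.concatenate([w, w]) if weighted else None,
            node_graph=np.concatenate(members),
            n_graphs=len(graphs),
        )

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


def _with_self_loops(batch: GraphBatch):
    loops = np.arange(batch.n_nodes, dtype=np.intp)
    src = np.concatenate([batch.edge_src, loops])
    dst = np.concatenate([batch.edge_dst, loops])
    if batch.edge_weight is not None:
        w = np.concatenate([batch.edge_weight, np.ones(batch.n_nodes)])
    else:
        w = np.ones(src.shape[0])
    return src, dst, w


def _gcn_coefficients(batch: GraphBatch):
    """Symmetric normalization D~^{-1/2} A~ D~^{-1/2} as edge coefficients."""
    src, dst, w = _with_self_loops(batch)
    deg = np.bincount(dst, weights=w, minlength=batch.n_nodes)
    inv_sqrt = 1.0 / np.sqrt(deg)
    return src, dst, w * inv_sqrt[src] * inv_sqrt[dst]


# ---------------------------------------------------------------------------
# parameters

def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)),
                  requires_grad=True)


class EncoderParams:
    """All learnable weights and configuration of one graph encoder."""

    def __init__(self, n_in: int, conv: str = "gcn", pooling: str = "max",
                 use_gate: bool = True, hidden_mult: int = 4,
                 proj_hidden: int = 1024, out_dim: int = EMBEDDING_DIM,
                 dropout: float = 0.2,
                 rng: np.random.Generator | None = None):
        if conv not in ("gcn", "gat"):
            raise ValueError(f"conv must be 'gcn' or 'gat', got {conv!r}")
        if pooling not in ("max", "mean"):
            raise ValueError(f"pooling must be 'max' or 'mean', got {pooling!r}")
        rng = rng or np.random.default_rng(0)
        self.n_in = n_in
        self.conv = conv
        self.pooling = pooling
        self.use_gate = use_gate
        self.dropout = dropout
        self.out_dim = out_dim
        h = hidden_mult * n_in
        self.hidden = h
        dims = [(n_in, h), (h, h), (h, h)]
        self.W = [_glorot(rng, a, b) for a, b in dims]
        if conv == "gat":
            self.a = [Tensor(rng.uniform(-0.1, 0.1, size=2 * b),
                             requires_grad=True) for _, b in dims]
        else:
            self.a = []
        # gates exist for the width-preserving layers 2 and 3
        self.U1 = [_glorot(rng, h, h) for _ in range(2)]
        self.U2 = [_glorot(rng, h, h) for _ in range(2)]
        self.gate_b = [Tensor(np.zeros(h), requires_grad=True)
                       for _ in range(2)]
        self.fc1_W = _glorot(rng, h, proj_hidden)
        self.fc1_b = Tensor(np.zeros(proj_hidden), requires_grad=True)
        self.fc2_W = _glorot(rng, proj_hidden, out_dim)
        self.fc2_b = Tensor(np.zeros(out_dim), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        ps = list(self.W) + list(self.a) + self.U1 + self.U2 + self.gate_b
        ps += [self.fc1_W, self.fc1_b, self.fc2_W, self.fc2_b]
        return ps

    def state_arrays(self) -> dict:
        out = {}
        for i, w in enumerate(self.W):
            out[f"W{i}"] = w.data
        for i, a in enumerate(self.a):
            out[f"a{i}"] = a.data
        for i in range(2):
            out[f"U1_{i}"] = self.U1[i].data
            out[f"U2_{i}"] = self.U2[i].data
            out[f"gate_b_{i}"] = self.gate_b[i].data
        out["fc1_W"] = self.fc1_W.data
        out["fc1_b"] = self.fc1_b.data
        out["fc2_W"] = self.fc2_W.data
        out["fc2_b"] = self.fc2_b.data
        return out

    def load_arrays(self, arrays: dict, prefix: str = "") -> None:
        for name, tensor in zip(
                [f"W{i}" for i in range(3)]
                + [f"a{i}" for i in range(len(self.a))]
                + [f"U1_{i}" for i in range(2)] + [f"U2_{i}" for i in range(2)]
                + [f"gate_b_{i}" for i in range(2)]
                + ["fc1_W", "fc1_b", "fc2_W", "fc2_b"],
                self.parameters()):
            tensor.data = np.asarray(arrays[prefix + name], dtype=float)


# ---------------------------------------------------------------------------
# layer forward passes (tensor-level)

def _gcn_forward(H: Tensor, src, dst, coef, W: Tensor, n_nodes: int) -> Tensor:
    HW = H @ W
    return spmm(coef, src, dst, n_nodes, HW).relu()


def _segment_softmax(e: Tensor, dst, n_nodes: int) -> Tensor:
    from ._autodiff import _scatter_max
    shift = _scatter_max(n_nodes, np.asarray(dst, dtype=np.intp),
                         e.data)
    ex = (e - shift[dst]).exp()
    denom = segment_sum(ex, dst, n_nodes)
    return ex / gather(denom, dst)


def _gat_forward(H: Tensor, src, dst, W: Tensor, a: Tensor,
                 n_nodes: int) -> Tensor:
    HW = H @ W
    F = W.data.shape[1]
    a_src = Tensor._make(a.data[:F], (a,),
                         lambda g: (np.concatenate([g, np.zeros(F)]),))
    a_dst = Tensor._make(a.data[F:], (a,),
                         lambda g: (np.concatenate([np.zeros(F), g]),))
    # logit for center i (= dst) and neighbor j (= src): a . [Wx_i || Wx_j]
    scores = gather(HW @ a_src, dst) + gather(HW @ a_dst, src)
    e = scores.leaky_relu(LEAKY_SLOPE)
    alpha = _segment_softmax(e, dst, n_nodes)
    return spmm(alpha, src, dst, n_nodes, HW).relu()


def _gated_skip_t(H_new: Tensor, H_old: Tensor, U1: Tensor, U2: Tensor,
                  b: Tensor) -> Tensor:
    z = (H_new @ U1 + H_old @ U2 + b).sigmoid()
    return z * H_new + (1.0 - z) * H_old


def _dropout(H: Tensor, rate: float, training: bool,
             rng: np.random.Generator | None) -> Tensor:
    if not training or rate <= 0.0:
        return H
    if rng is None:
        raise ValueError("training-mode dropout needs an rng")
    mask = (rng.random(H.data.shape) >= rate) / (1.0 - rate)
    return H * mask


def encode_batch(batch: GraphBatch, params: EncoderParams,
                 training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
    """Encode every graph in the batch into a row of a (G, 128) tensor."""
    if batch.node_features.shape[1] != params.n_in:
        raise ShapeError(
            f"feature width {batch.node_features.shape[1]} != encoder "
            f"input width {params.n_in}")
    n = batch.n_nodes
    if params.conv == "gcn":
        src, dst, coef = _gcn_coefficients(batch)
    else:
        src, dst, _ = _with_self_loops(batch)
        coef = None
    H = Tensor(batch.node_features)
    prev = None
    for layer in range(3):
        if params.conv == "gcn":
            H_new = _gcn_forward(H, src, dst, coef, params.W[layer], n)
        else:
            H_new = _gat_forward(H, src, dst, params.W[layer],
                                 params.a[layer], n)
        if layer >= 1 and params.use_gate:
            H_new = _gated_skip_t(H_new, H, params.U1[layer - 1],
                                  params.U2[layer - 1],
                                  params.gate_b[layer - 1])
        prev, H = H, H_new
    if params.pooling == "max":
        pooled = segment_max(H, batch.node_graph, batch.n_graphs)
    else:
        pooled = segment_mean(H, batch.node_graph, batch.n_graphs)
    out = (pooled @ params.fc1_W + params.fc1_b).relu()
    out = _dropout(out, params.dropout, training, rng)
    out = out @ params.fc2_W + params.fc2_b
    out = _dropout(out, params.dropout, training, rng)
    return out


def encode(graph: AtomGraph | MotifGraph | WeightedProteinGraph,
           params: EncoderParams, training: bool = False,
           rng: np.random.Generator | None = None) -> np.ndarray:
    """Encode a single graph into a 128-dimensional vector."""
    if graph.n_nodes == 0:
        raise ShapeError("cannot encode an empty graph")
    batch = GraphBatch.from_graphs([graph])
    return encode_batch(batch, params, training=training, rng=rng).data[0]


# ---------------------------------------------------------------------------
# functional single-layer API (NumPy in, NumPy out)

def _dense_to_batch(H: np.ndarray, A: np.ndarray) -> GraphBatch:
    H = np.asarray(H, dtype=float)
    A = np.asarray(A, dtype=float)
    n = H.shape[0]
    if A.shape != (n, n):
        raise ShapeError(f"adjacency shape {A.shape} does not match "
                         f"{n} nodes")
    if not np.allclose(A, A.T):
        raise ShapeError("adjacency must be symmetric")
    iu, ju = np.triu_indices(n, k=1)
    keep = A[iu, ju] != 0
    edges = list(zip(iu[keep].tolist(), ju[keep].tolist()))
    weights = A[iu, ju][keep]

    class _G:
        n_nodes = n
        node_features = H

    g = _G()
    g.edges = edges
    g.edge_weights = weights
    return GraphBatch.from_graphs([g])


def gcn_layer(H: np.ndarray, A: np.ndarray, W: np.ndarray) -> np.ndarray:
    """One GCN propagation: ReLU(D~^{-1/2} A~ D~^{-1/2} H W), A~ = A + I.

    Nonzero entries of ``A`` act as edge weights (the weighted protein
    graph); a 0/1 adjacency reproduces the unweighted update.
    """
    batch = _dense_to_batch(H, A)
    W = np.asarray(W, dtype=float)
    if W.shape[0] != batch.node_features.shape[1]:
        raise ShapeError("weight matrix rows must match feature width")
    src, dst, coef = _gcn_coefficients(batch)
    return _gcn_forward(Tensor(batch.node_features), src, dst, coef,
                        Tensor(W), batch.n_nodes).data


def gat_layer(H: np.ndarray, A: np.ndarray, W: np.ndarray,
              a: np.ndarray) -> np.ndarray:
    """One single-head GAT layer; neighborhoods include the node itself."""
    batch = _dense_to_batch(H, A)
    W = np.asarray(W, dtype=float)
    a = np.asarray(a, dtype=float)
    if a.shape[0] != 2 * W.shape[1]:
        raise ShapeError("attention vector must have length 2*F'")
    src, dst, _ = _with_self_loops(batch)
    return _gat_forward(Tensor(batch.node_features), src, dst, Tensor(W),
                        Tensor(a), batch.n_nodes).data


def gat_attention(H: np.ndarray, A: np.ndarray, W: np.ndarray,
                  a: np.ndarray) -> np.ndarray:
    """Dense (i, j) attention matrix of one GAT layer, rows summing to 1
    over each node's (self-inclusive) neighborhood."""
    batch = _dense_to_batch(H, A)
    src, dst, _ = _with_self_loops(batch)
    HW = batch.node_features @ np.asarray(W, dtype=float)
    F = HW.shape[1]
    a = np.asarray(a, dtype=float)
    scores = HW[dst] @ a[:F] + HW[src] @ a[F:]
    e = np.where(scores > 0, scores, LEAKY_SLOPE * scores)
    alpha = _segment_softmax(Tensor(e), dst, batch.n_nodes).data
    dense = np.zeros((batch.n_nodes, batch.n_nodes))
    dense[dst, src] = alpha
    return dense


def gated_skip(H_new: np.ndarray, H_old: np.ndarray, U1: np.ndarray,
               U2: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Gated skip-connection: sigmoid gate interpolating new and old
    features elementwise."""
    H_new = np.asarray(H_new, dtype=float)
    H_old = np.asarray(H_old, dtype=float)
    if H_new.shape != H_old.shape:
        raise ShapeError("gated_skip inputs must share a shape")
    return _gated_skip_t(Tensor(H_new), Tensor(H_old),
                         Tensor(np.asarray(U1, dtype=float)),
                         Tensor(np.asarray(U2, dtype=float)),
                         Tensor(np.asarray(b, dtype=float))).data
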