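"""Attention fusion of branch embeddings and the affinity regression head.

The three 128-dimensional branch embeddings (drug atom graph Z_d, drug
motif graph Z_m, protein graph Z_p) are fused adaptively: a shared
two-stage scorer w_i = W2 . tanh(W1 . Z_i) produces one scalar per
branch, a three-way softmax turns the scores into attention weights
alpha, and the weighted embeddings are concatenated,

    Zc = [alpha_d Z_d || alpha_m Z_m || alpha_p Z_p].

Zc feeds a three-layer fully-connected head (384 -> 1024 -> 512 -> 1,
ReLU activations, dropout after the hidden stages, linear output) that
predicts the binding affinity.

Ablation switches reproduce the reduced variants: ``use_attention=False``
concatenates the raw embeddings (equal implicit weights),
``use_motif=False`` drops the motif branch entirely (head input 256) and
``use_skip=False`` disables the encoders' gated skip-connections.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np

from ._autodiff import Tensor, concat, gather
from .drug_graphs import (ATOM_FEATURE_DIM, MOTIF_FEATURE_DIM,
                          FeatureVocabulary)
from .gnn_encoder import (EMBEDDING_DIM, EncoderParams, GraphBatch, ShapeError,
                          _dropout, _glorot, encode_batch)
from .protein_graphs import RESIDUE_FEATURE_DIM

HEAD_HIDDEN = (1024, 512)


class FusionParams:
    """Learnable weights of the attention scorer and the FC head."""

    def __init__(self, n_branches: int = 3, att_dim: int = EMBEDDING_DIM,
                 dropout: float = 0.2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.n_branches = n_branches
        self.dropout = dropout
        self.W1 = _glorot(rng, EMBEDDING_DIM, att_dim)
        self.W2 = Tensor(rng.uniform(-0.1, 0.1, size=att_dim),
                         requires_grad=True)
        in_dim = n_branches * EMBEDDING_DIM
        dims = (in_dim,) + HEAD_HIDDEN + (1,)
        self.head_W = [_glorot(rng, a, b) for a, b in zip(dims, dims[1:])]
        self.head_b = [Tensor(np.zeros(b), requires_grad=True)
                       for b in dims[1:]]

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.W2] + self.head_W + self.head_b

    def state_arrays(self) -> dict:
        out = {"W1": self.W1.data, "W2": self.W2.data}
        for i, (w, b) in enumerate(zip(self.head_W, self.head_b)):
            out[f"head_W{i}"] = w.data
            out[f"head_b{i}"] = b.data
        return out

    def load_arrays(self, arrays: dict, prefix: str = "") -> None:
        self.W1.data = np.asarray(arrays[prefix + "W1"], dtype=float)
        self.W2.data = np.asarray(arrays[prefix + "W2"], dtype=float)
        for i in range(len(self.head_W)):
            self.head_W[i].data = np.asarray(arrays[f"{prefix}head_W{i}"],
                                             dtype=float)
            self.head_b[i].data = np.asarray(arrays[f"{prefix}head_b{i}"],
                                             dtype=float)


def _branch_scores(Zs: list[Tensor], params: FusionParams) -> list[Tensor]:
    return [(Z @ params.W1).tanh() @ params.W2 for Z in Zs]


def _softmax_rows(ws: list[Tensor]) -> list[Tensor]:
    shift = np.max([w.data for w in ws], axis=0)
    exps = [(w - shift).exp() for w in ws]
    denom = exps[0]
    for e in exps[1:]:
        denom = denom + e
    return [e / denom for e in exps]


def fuse_batch(Zs: list[Tensor], params: FusionParams,
               use_attention: bool = True):
    """Fuse (B, 128) branch tensors into a (B, n*128) tensor and the
    (B, n) attention weights (identity weights when attention is off)."""
    if use_attention:
        alphas = _softmax_rows(_branch_scores(Zs, params))
        fused = concat([a.reshape(-1, 1) * Z for a, Z in zip(alphas, Zs)],
                       axis=1)
        alpha_data = np.stack([a.data for a in alphas], axis=1)
    else:
        fused = concat(Zs, axis=1)
        alpha_data = np.ones((Zs[0].data.shape[0], len(Zs)))
    return fused, alpha_data


def head_batch(Zc: Tensor, params: FusionParams, training: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
    """FC head on a (B, in_dim) tensor; returns a (B,) tensor."""
    h = Zc
    last = len(params.head_W) - 1
    for i, (W, b) in enumerate(zip(params.head_W, params.head_b)):
        h = h @ W + b
        if i < last:
            h = h.relu()
            h = _dropout(h, params.dropout, training, rng)
    return h.reshape(-1)


def attention_fuse(Zd: np.ndarray, Zm: np.ndarray, Zp: np.ndarray,
                   params: FusionParams):
    """Fuse three 128-vectors; returns (Zc, alpha) as NumPy arrays."""
    Zs = [Tensor(np.asarray(Z, dtype=float).reshape(1, -1))
          for Z in (Zd, Zm, Zp)]
    for Z in Zs:
        if Z.data.shape[1] != EMBEDDING_DIM:
            raise ShapeError("branch embeddings must have length "
                             f"{EMBEDDING_DIM}")
    fused, alpha = fuse_batch(Zs, params, use_attention=True)
    return fused.data[0], alpha[0]


def predict_affinity(Zc: np.ndarray, params: FusionParams,
                     training: bool = False,
                     rng: np.random.Generator | None = None) -> float:
    """Scalar affinity from a fused vector."""
    Zc = np.asarray(Zc, dtype=float).reshape(1, -1)
    if Zc.shape[1] != params.head_W[0].data.shape[0]:
        raise ShapeError(
            f"fused vector length {Zc.shape[1]} != head input width "
            f"{params.head_W[0].data.shape[0]}")
    return float(head_batch(Tensor(Zc), params, training, rng).data[0])


class DTAPredictor:
    """Three-branch graph model predicting drug-target binding affinity."""

    def __init__(self, conv: str = "gat", pooling: str = "max",
                 use_attention: bool = True, use_motif: bool = True,
                 use_skip: bool = True, dropout: float = 0.2,
                 seed: int = 0,
                 vocab: FeatureVocabulary | None = None):
        rng = np.random.default_rng(seed)
        self.config = {
            "conv": conv, "pooling": pooling,
            "use_attention": use_attention, "use_motif": use_motif,
            "use_skip": use_skip, "dropout": dropout, "seed": seed,
        }
        self.vocab = vocab or FeatureVocabulary()
        common = dict(conv=conv, pooling=pooling, use_gate=use_skip,
                      dropout=dropout)
        self.atom_encoder = EncoderParams(ATOM_FEATURE_DIM, rng=rng, **common)
        self.motif_encoder = EncoderParams(MOTIF_FEATURE_DIM, rng=rng,
                                           **common)
        self.protein_encoder = EncoderParams(RESIDUE_FEATURE_DIM, rng=rng,
                                             **common)
        self.fusion = FusionParams(n_branches=3 if use_motif else 2,
                                   dropout=dropout, rng=rng)

    # -- forward --------------------------------------------------------
    def forward_batch(self, atom_batch: GraphBatch, motif_batch: GraphBatch,
                      protein_batch: GraphBatch, training: bool = False,
                      rng: np.random.Generator | None = None,
                      atom_index: np.ndarray | None = None,
                      motif_index: np.ndarray | None = None,
                      protein_index: np.ndarray | None = None) -> Tensor:
        """Predicted affinities, one per packed graph triple.

        Optional ``*_index`` arrays map records to rows of a batch of
        unique graphs, so a drug or protein shared by several records in
        the batch is encoded once.
        """
        Zd = encode_batch(atom_batch, self.atom_encoder, training, rng)
        if atom_index is not None:
            Zd = gather(Zd, atom_index)
        Zp = encode_batch(protein_batch, self.protein_encoder, training, rng)
        if protein_index is not None:
            Zp = gather(Zp, protein_index)
        if self.config["use_motif"]:
            Zm = encode_batch(motif_batch, self.motif_encoder, training, rng)
            if motif_index is not None:
                Zm = gather(Zm, motif_index)
            Zs = [Zd, Zm, Zp]
        else:
            Zs = [Zd, Zp]
        fused, self.last_alpha = fuse_batch(
            Zs, self.fusion, use_attention=self.config["use_attention"])
        return head_batch(fused, self.fusion, training, rng)

    def predict_graphs(self, atom_graph, motif_graph,
                       protein_graph) -> float:
        """Deterministic eval-mode prediction for one drug-protein pair."""
        return float(self.forward_batch(
            GraphBatch.from_graphs([atom_graph]),
            GraphBatch.from_graphs([motif_graph]),
            GraphBatch.from_graphs([protein_graph])).data[0])

    # -- parameter plumbing ---------------------------------------------
    def parameters(self) -> list[Tensor]:
        ps = (self.atom_encoder.parameters()
              + self.protein_encoder.parameters())
        if self.config["use_motif"]:
            ps += self.motif_encoder.parameters()
        return ps + self.fusion.parameters()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> dict:
        out = {}
        for name, enc in (("atom", self.atom_encoder),
                          ("motif", self.motif_encoder),
                          ("protein", self.protein_encoder)):
            for k, v in enc.state_arrays().items():
                out[f"{name}/{k}"] = v
        for k, v in self.fusion.state_arrays().items():
            out[f"fusion/{k}"] = v
        return out

    def load_state(self, arrays: dict) -> None:
        self.atom_encoder.load_arrays(arrays, "atom/")
        self.motif_encoder.load_arrays(arrays, "motif/")
        self.protein_encoder.load_arrays(arrays, "protein/")
        self.fusion.load_arrays(arrays, "fusion/")

    def vocabulary_hash(self) -> str:
        blob = json.dumps(self.vocab.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # -- checkpointing ---------------------------------------------------
    def save(self, path) -> None:
        meta = json.dumps({"config": self.config,
                           "vocab": self.vocab.to_dict(),
                           "vocab_hash": self.vocabulary_hash()})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.state_arrays())

    @classmethod
    def load(cls, path) -> "DTAPredictor":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"].tolist()).decode())
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        model = cls(vocab=FeatureVocabulary.from_dict(meta["vocab"]),
                    **meta["config"])
        model.load_state(arrays)
        return model


def forward(record, cache, model: DTAPredictor) -> float:
    """Full pipeline on one dataset record using prebuilt graphs.

    ``cache`` must expose ``drug_graphs[drug_id] -> (AtomGraph,
    MotifGraph)`` and ``protein_graphs[protein_id] -> WeightedProteinGraph``.
    """
    try:
        atom_g, motif_g = cache.drug_graphs[record.drug_id]
    except KeyError:
        raise KeyError(f"no cached graphs for drug id {record.drug_id!r}")
    try:
        prot_g = cache.protein_graphs[record.protein_id]
    except KeyError:
        raise KeyError(f"no cached graph for protein id {record.protein_id!r}")
    return model.predict_graphs(atom_g, motif_g, prot_g)
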