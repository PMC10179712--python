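"""Mini-batch Adam training of the three-branch affinity model.

The loss is the mean squared error between predicted and true
affinities.  Graphs are built once per unique drug and protein
(`GraphCache`) and packed into disjoint-union batches per step.  All
randomness (shuffling, dropout, initialization) is driven by one seed.
The head's output bias is initialized at the mean training label so
optimization starts from the best constant predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor
from .drug_graphs import FeatureVocabulary, build_atom_graph, build_motif_graph
from .fusion_head import DTAPredictor
from .gnn_encoder import GraphBatch
from .metrics import evaluate_all, mse
from .protein_graphs import ContactPredictor, build_protein_graph


@dataclass
class GraphCache:
    """Prebuilt graphs keyed by drug and protein id."""

    drug_graphs: dict = field(default_factory=dict)
    protein_graphs: dict = field(default_factory=dict)


def prepare_graphs(records, contact_predictor: ContactPredictor,
                   vocab: FeatureVocabulary | None = None,
                   threshold: float = 0.5,
                   windowsize: int = 500) -> GraphCache:
    """Build every unique drug and protein graph appearing in `records`."""
    vocab = vocab or FeatureVocabulary()
    cache = GraphCache()
    for r in records:
        if r.drug_id not in cache.drug_graphs:
            cache.drug_graphs[r.drug_id] = (
                build_atom_graph(r.smiles, vocab),
                build_motif_graph(r.smiles, vocab))
        if r.protein_id not in cache.protein_graphs:
            cache.protein_graphs[r.protein_id] = build_protein_graph(
                r.sequence, contact_predictor, threshold=threshold,
                windowsize=windowsize)
    return cache


def _unique_index(keys):
    uniq = list(dict.fromkeys(keys))
    pos = {k: i for i, k in enumerate(uniq)}
    return uniq, np.array([pos[k] for k in keys], dtype=np.intp)


def _batches_for(records, cache: GraphCache):
    """Batches of *unique* graphs plus record->row index maps, so shared
    drugs/proteins inside a minibatch are encoded once."""
    drug_ids = [r.drug_id for r in records]
    prot_ids = [r.protein_id for r in records]
    uniq_d, idx_d = _unique_index(drug_ids)
    uniq_p, idx_p = _unique_index(prot_ids)
    atom = GraphBatch.from_graphs([cache.drug_graphs[d][0] for d in uniq_d])
    motif = GraphBatch.from_graphs([cache.drug_graphs[d][1] for d in uniq_d])
    prot = GraphBatch.from_graphs(
        [cache.protein_graphs[p] for p in uniq_p])
    return (atom, motif, prot), (idx_d, idx_d, idx_p)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad ** 2
            p.data -= self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps)


def predict_records(model: DTAPredictor, records, cache: GraphCache,
                    batch_size: int = 64) -> np.ndarray:
    """Deterministic eval-mode predictions, in record order."""
    preds = []
    for i in range(0, len(records), batch_size):
        chunk = records[i:i + batch_size]
        (atom, motif, prot), (ia, im, ip) = _batches_for(chunk, cache)
        preds.append(model.forward_batch(
            atom, motif, prot, atom_index=ia, motif_index=im,
            protein_index=ip).data)
    return np.concatenate(preds)


def fit(model: DTAPredictor, train_records, cache: GraphCache,
        epochs: int = 200, batch_size: int = 16, lr: float = 2e-3,
        seed: int = 0, val_records=None, log_path=None,
        keep_best_val: bool = True) -> list[dict]:
    """Train the model in place; returns the per-epoch history.

    When ``val_records`` is given, the parameter state with the lowest
    validation MSE is restored at the end (``keep_best_val``).
    """
    rng = np.random.default_rng(seed)
    labels = np.array([r.affinity for r in train_records])
    model.fusion.head_b[-1].data[:] = labels.mean()
    opt = Adam(model.parameters(), lr=lr)
    history: list[dict] = []
    best = (np.inf, None)
    log_file = open(log_path, "w") if log_path else None
    try:
        for epoch in range(epochs):
            order = rng.permutation(len(train_records))
            sq_sum = 0.0
            for lo in range(0, len(order), batch_size):
                idx = order[lo:lo + batch_size]
                chunk = [train_records[i] for i in idx]
                (atom, motif, prot), (ia, im, ip) = _batches_for(chunk, cache)
                pred = model.forward_batch(
                    atom, motif, prot, training=True, rng=rng,
                    atom_index=ia, motif_index=im, protein_index=ip)
                diff = pred - labels[idx]
                loss = (diff * diff).mean()
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch "
                        f"{epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                sq_sum += float(loss.data) * len(idx)
            entry = {"epoch": epoch,
                     "train_mse": sq_sum / len(train_records)}
            if val_records:
                val_pred = predict_records(model, val_records, cache)
                val_true = [r.affinity for r in val_records]
                entry["val_mse"] = mse(val_true, val_pred)
                if entry["val_mse"] < best[0]:
                    best = (entry["val_mse"],
                            {k: v.copy()
                             for k, v in model.state_arrays().items()})
            history.append(entry)
            if log_file:
                log_file.write(json.dumps(entry) + "\n")
    finally:
        if log_file:
            log_file.close()
    if val_records and keep_best_val and best[1] is not None:
        model.load_state(best[1])
    return history


def evaluate_split(model: DTAPredictor, records, cache: GraphCache) -> dict:
    preds = predict_records(model, records, cache)
    return evaluate_all([r.affinity for r in records], preds)
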