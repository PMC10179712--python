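"""Self-contained synthetic fixtures: drugs, proteins, contacts, labels.

Everything needed to exercise the full pipeline without downloads.
Molecules are assembled from a curated vocabulary of valid SMILES
fragments (rings and acyclic units) joined at attachment points, so
every generated string parses and both motif kinds occur.  Protein
sequences are drawn over the 20 standard residues with a length range
that straddles the 1000-residue window limit so contact-map splicing is
exercised.  Contact predictors come in three deterministic stub
flavours.  Affinity labels carry a known linear dependence on graph
features visible to the three model branches,

    raw = a * (drug ring count) + b * (sequence length / max length)
        + c * (fraction of residues whose letter is also an element of
               the drug),

affinely rescaled into a Davis-like pKd range plus Gaussian noise; the
coefficients and the noiseless values are recorded in a manifest so
recovery tests know the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .data_io import DTARecord
from .protein_graphs import ContactPredictor

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

RING_FRAGMENTS = (
    "c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCOC1", "C1CCNC1",
    "c1ccc2ccccc2c1", "c1ccsc1", "C1CCNCC1",
)
CHAIN_FRAGMENTS = (
    "C", "CC", "CO", "CN", "CCO", "C(=O)O", "C(C)C", "CCl", "C(=O)N",
    "OC", "S", "CCN", "C(F)(F)F",
)


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic benchmark."""

    n_drugs: int = 16
    n_proteins: int = 8
    n_pairs: int = 64
    seq_len_range: tuple = (60, 1100)   # straddles the 1000-residue cap
    noise_sd: float = 0.1
    seed: int = 0
    coeff_ring: float = 1.0
    coeff_len: float = 1.0
    coeff_shared: float = 1.0
    affinity_range: tuple = (5.0, 10.8)  # Davis-like pKd span
    ring_fragments: tuple = RING_FRAGMENTS
    chain_fragments: tuple = CHAIN_FRAGMENTS

    def __post_init__(self):
        if min(self.n_drugs, self.n_proteins, self.n_pairs) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_pairs > self.n_drugs * self.n_proteins:
            raise ValueError("n_pairs exceeds the number of distinct pairs")


def gen_molecules(cfg: SyntheticConfig) -> list[str]:
    """Fragment-assembled SMILES; all parseable, both motif kinds occur.

    The first molecule is forced acyclic and the second ring-containing.
    """
    from rdkit import RDLogger
    rng = np.random.default_rng(cfg.seed)
    out = []
    RDLogger.DisableLog("rdApp.error")  # invalid assemblies are retried
    try:
        out = _assemble(cfg, rng)
    finally:
        RDLogger.EnableLog("rdApp.error")
    return out


def _assemble(cfg: SyntheticConfig, rng) -> list[str]:
    out = []
    for i in range(cfg.n_drugs):
        while True:
            n_frag = int(rng.integers(2, 5))
            if i == 0:
                pool = cfg.chain_fragments
                frags = [pool[k] for k in rng.integers(0, len(pool),
                                                       size=n_frag)]
            else:
                frags = []
                for _ in range(n_frag):
                    if rng.random() < 0.4:
                        pool = cfg.ring_fragments
                    else:
                        pool = cfg.chain_fragments
                    frags.append(pool[int(rng.integers(0, len(pool)))])
                if i == 1 and not any(f in cfg.ring_fragments
                                      for f in frags):
                    frags[0] = cfg.ring_fragments[
                        int(rng.integers(0, len(cfg.ring_fragments)))]
            smiles = "".join(frags)
            if Chem.MolFromSmiles(smiles) is not None:
                out.append(smiles)
                break
    return out


def gen_proteins(cfg: SyntheticConfig) -> list[str]:
    """Random sequences over the 20 standard residues.

    When the configured range allows, the first sequence is pinned to
    the range maximum so at least one protein exercises the windowed
    contact-map assembly.
    """
    lo, hi = cfg.seq_len_range
    if not (2 <= lo <= hi):
        raise ValueError("invalid sequence length range")
    rng = np.random.default_rng(cfg.seed + 1)
    lengths = rng.integers(lo, hi + 1, size=cfg.n_proteins)
    if hi > 1000:
        lengths[0] = hi
    letters = np.array(list(STANDARD_AA))
    return ["".join(letters[rng.integers(0, len(letters), size=int(L))])
            for L in lengths]


def stub_contact_predictor(kind: str = "banded", value: float = 0.9,
                           scale: float = 6.0) -> ContactPredictor:
    """Deterministic, symmetric, [0,1]-valued contact predictor stubs.

    ``constant``  — every cell equals ``value``.
    ``banded``    — exp(-|i-j|/scale): probability decays with sequence
                    separation, so thresholding yields a near-diagonal
                    graph (a crude secondary-structure caricature).
    ``hash``      — a deterministic pseudo-random function of the
                    window-local indices and residue letters, so
                    overlapping windows genuinely disagree and the
                    splice-and-average path is exercised.
    """
    if kind == "constant":
        def predictor(seq: str) -> np.ndarray:
            L = len(seq)
            return np.full((L, L), float(value))
    elif kind == "banded":
        def predictor(seq: str) -> np.ndarray:
            idx = np.arange(len(seq))
            return np.exp(-np.abs(idx[:, None] - idx[None, :]) / scale)
    elif kind == "hash":
        def predictor(seq: str) -> np.ndarray:
            idx = np.arange(len(seq))
            codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            codes = codes.astype(float) - 64.0
            s = (idx[:, None] + idx[None, :]) * 12.9898
            prod = (idx[:, None] * idx[None, :]) * 0.02331
            let = (codes[:, None] + codes[None, :]) * 3.7177
            vals = np.sin(s + prod + let) * 43758.5453
            return vals - np.floor(vals)
    else:
        raise ValueError(f"unknown stub kind {kind!r}")
    return predictor


def _ring_count(smiles: str) -> int:
    return Chem.MolFromSmiles(smiles).GetRingInfo().NumRings()


def _element_letters(smiles: str) -> set:
    mol = Chem.MolFromSmiles(smiles)
    return {a.GetSymbol().upper() for a in mol.GetAtoms()
            if len(a.GetSymbol()) == 1}


def _shared_fraction(sequence: str, smiles: str) -> float:
    elems = _element_letters(smiles)
    return sum(1 for a in sequence if a in elems) / len(sequence)


def gen_affinities(drugs: list[str], proteins: list[str],
                   cfg: SyntheticConfig):
    """Sample distinct pairs and label them; returns (records, manifest)."""
    if not drugs or not proteins:
        raise ValueError("need at least one drug and one protein")
    rng = np.random.default_rng(cfg.seed + 2)
    all_pairs = [(d, p) for d in range(len(drugs))
                 for p in range(len(proteins))]
    chosen = rng.choice(len(all_pairs), size=cfg.n_pairs, replace=False)
    max_len = max(len(s) for s in proteins)
    raw = []
    for k in chosen:
        d, p = all_pairs[k]
        raw.append(cfg.coeff_ring * _ring_count(drugs[d])
                   + cfg.coeff_len * len(proteins[p]) / max_len
                   + cfg.coeff_shared * _shared_fraction(proteins[p],
                                                         drugs[d]))
    raw = np.asarray(raw)
    lo, hi = cfg.affinity_range
    span = raw.max() - raw.min()
    if span == 0.0:
        slope, intercept = 0.0, (lo + hi) / 2.0
    else:
        slope = (hi - lo) / span
        intercept = lo - slope * raw.min()
    clean = slope * raw + intercept
    noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_pairs)
    records, entries = [], []
    for j, k in enumerate(chosen):
        d, p = all_pairs[k]
        records.append(DTARecord(
            drug_id=f"D{d:03d}", smiles=drugs[d],
            protein_id=f"P{p:03d}", sequence=proteins[p],
            affinity=float(clean[j] + noise[j])))
        entries.append({
            "drug_id": f"D{d:03d}", "protein_id": f"P{p:03d}",
            "raw": float(raw[j]), "clean_affinity": float(clean[j]),
            "affinity": float(clean[j] + noise[j]),
        })
    manifest = {
        "seed": cfg.seed,
        "coefficients": {"ring": cfg.coeff_ring, "len": cfg.coeff_len,
                         "shared": cfg.coeff_shared},
        "scale": {"slope": float(slope), "intercept": float(intercept),
                  "max_len": max_len},
        "noise_sd": cfg.noise_sd,
        "affinity_range": list(cfg.affinity_range),
        "records": entries,
    }
    return records, manifest


def gen_dataset(cfg: SyntheticConfig):
    """Full synthetic dataset: (records, sequences-by-id, manifest)."""
    drugs = gen_molecules(cfg)
    proteins = gen_proteins(cfg)
    records, manifest = gen_affinities(drugs, proteins, cfg)
    sequences = {f"P{i:03d}": s for i, s in enumerate(proteins)}
    manifest["n_drugs"] = cfg.n_drugs
    manifest["n_proteins"] = cfg.n_proteins
    return records, sequences, manifest


def save_dataset(records, sequences, manifest, out_dir) -> None:
    from pathlib import Path

    from .data_io import save_long_table, write_fasta
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_long_table(records, out / "pairs.tsv")
    write_fasta(sequences, out / "proteins.fasta")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
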