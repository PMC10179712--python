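"""Atom-level and motif-level molecular graphs from SMILES.

A drug is represented at two resolutions.  The *atom graph* has one node
per heavy atom (hydrogens are implicit and enter only through the H-count
feature block) and one edge per chemical bond; each node carries a
78-dimensional binary/ordinal feature vector.  The *motif graph* is a
coarsening in which every perceived ring (smallest set of smallest rings)
and every bond outside any ring — together with its two end atoms — is a
node; each motif node carries a 92-dimensional feature vector.  Motif
nodes are adjacent when they share an atom or are joined by a bond.

Feature layout (atom, 78 = 44+11+11+11+1):
    one-hot element symbol (44, last slot = unknown) |
    one-hot heavy-atom degree (0..10) | one-hot total H count (0..10) |
    one-hot implicit valence (0..10) | aromatic flag.

Feature layout (motif, 92 = 44+11+11+12+12+1+1):
    multi-hot element symbols present | one-hot atom count (0..10) |
    one-hot inter-motif edge count (0..10) | one-hot total H (0..11) |
    one-hot summed implicit valence (0..11) | simple-ring flag |
    bond-unit flag.

Counts beyond a block's range clamp to its final bin, so featurization is
total on any valid molecule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

ATOM_FEATURE_DIM = 78
MOTIF_FEATURE_DIM = 92

# Common-organic + metal element vocabulary, as conventionally used by
# graph-based DTA models; the final "X" slot absorbs anything else.
DEFAULT_ATOM_SYMBOLS = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca",
    "Fe", "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag",
    "Pd", "Co", "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni",
    "Cd", "In", "Mn", "Zr", "Cr", "Pt", "Hg", "Pb", "X",
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class FeatureVocabulary:
    """Fixed encoding tables for atom and motif featurization.

    Serialized with any trained model so feature layouts are reproducible.
    """

    atom_symbols: tuple = DEFAULT_ATOM_SYMBOLS
    degree_bins: int = 11          # heavy-atom degree 0..10
    h_count_bins: int = 11         # atoms: total H 0..10
    valence_bins: int = 11         # atoms: implicit valence 0..10
    motif_count_bins: int = 11     # motif atom count / inter-motif degree 0..10
    motif_h_bins: int = 12         # motif total H 0..11
    motif_valence_bins: int = 12   # motif summed implicit valence 0..11

    def __post_init__(self):
        if len(self.atom_symbols) != 44:
            raise ValueError("atom symbol vocabulary must have 44 slots")

    def symbol_index(self, symbol: str) -> int:
        try:
            return self.atom_symbols.index(symbol)
        except ValueError:
            return len(self.atom_symbols) - 1  # unknown slot

    def to_dict(self) -> dict:
        return {
            "atom_symbols": list(self.atom_symbols),
            "degree_bins": self.degree_bins,
            "h_count_bins": self.h_count_bins,
            "valence_bins": self.valence_bins,
            "motif_count_bins": self.motif_count_bins,
            "motif_h_bins": self.motif_h_bins,
            "motif_valence_bins": self.motif_valence_bins,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureVocabulary":
        d = dict(d)
        d["atom_symbols"] = tuple(d["atom_symbols"])
        return cls(**d)


def _one_hot(value: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[min(int(value), size - 1)] = 1.0  # clamp to last bin
    return v


@dataclass
class AtomGraph:
    """Heavy-atom graph of one drug molecule."""

    n_nodes: int
    node_features: np.ndarray          # (n_nodes, 78)
    edges: list                        # unordered pairs (i, j), i < j
    smiles: str

    def to_json(self) -> str:
        return json.dumps({
            "kind": "atom_graph",
            "smiles": self.smiles,
            "n_nodes": self.n_nodes,
            "edges": [list(e) for e in self.edges],
            "node_features": self.node_features.tolist(),
        })

    @classmethod
    def from_json(cls, s: str) -> "AtomGraph":
        d = json.loads(s)
        return cls(
            n_nodes=d["n_nodes"],
            node_features=np.asarray(d["node_features"], dtype=float),
            edges=[tuple(e) for e in d["edges"]],
            smiles=d["smiles"],
        )


@dataclass(frozen=True)
class Motif:
    """A coarse structural unit: a perceived ring or a non-ring bond.

    ``atoms`` are source heavy-atom indices, ``bonds`` the bonds assigned
    to this motif (each molecular bond is assigned to exactly one motif),
    ``kind`` is "ring" or "bond".
    """

    atoms: frozenset
    bonds: frozenset
    kind: str


@dataclass
class MotifGraph:
    """Coarse ring/bond-unit graph of one drug molecule."""

    n_nodes: int
    node_features: np.ndarray          # (n_nodes, 92)
    edges: list
    motif_atoms: list                  # per-node frozenset of atom indices
    motif_kind: list                   # per-node "ring" | "bond"
    smiles: str

    def to_json(self) -> str:
        return json.dumps({
            "kind": "motif_graph",
            "smiles": self.smiles,
            "n_nodes": self.n_nodes,
            "edges": [list(e) for e in self.edges],
            "motif_atoms": [sorted(a) for a in self.motif_atoms],
            "motif_kind": list(self.motif_kind),
            "node_features": self.node_features.tolist(),
        })

    @classmethod
    def from_json(cls, s: str) -> "MotifGraph":
        d = json.loads(s)
        return cls(
            n_nodes=d["n_nodes"],
            node_features=np.asarray(d["node_features"], dtype=float),
            edges=[tuple(e) for e in d["edges"]],
            motif_atoms=[frozenset(a) for a in d["motif_atoms"]],
            motif_kind=list(d["motif_kind"]),
            smiles=d["smiles"],
        )


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    if mol.GetNumHeavyAtoms() < 1:
        raise SmilesParseError(f"molecule has no heavy atoms: {smiles!r}")
    return mol


def featurize_atom(atom: Chem.Atom,
                   vocab: FeatureVocabulary | None = None) -> np.ndarray:
    """78-dim feature vector of one heavy atom.

    Four one-hot blocks (symbol, degree, total H, implicit valence) plus
    an aromatic flag; the row sums to 4 for non-aromatic and 5 for
    aromatic atoms.
    """
    vocab = vocab or FeatureVocabulary()
    sym = np.zeros(len(vocab.atom_symbols))
    sym[vocab.symbol_index(atom.GetSymbol())] = 1.0
    return np.concatenate([
        sym,
        _one_hot(atom.GetDegree(), vocab.degree_bins),
        _one_hot(atom.GetTotalNumHs(), vocab.h_count_bins),
        _one_hot(atom.GetImplicitValence(), vocab.valence_bins),
        [1.0 if atom.GetIsAromatic() else 0.0],
    ])


def build_atom_graph(smiles: str,
                     vocab: FeatureVocabulary | None = None) -> AtomGraph:
    """Build the heavy-atom graph of a molecule from its SMILES."""
    vocab = vocab or FeatureVocabulary()
    mol = _parse(smiles)
    features = np.stack([featurize_atom(a, vocab) for a in mol.GetAtoms()])
    edges = sorted(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
         max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    return AtomGraph(mol.GetNumAtoms(), features, edges, smiles)


def decompose_motifs(smiles: str) -> list[Motif]:
    """Split a molecule into ring motifs and non-ring bond-unit motifs.

    Rings come from SSSR perception, one motif per ring.  Every bond not
    inside a ring becomes a two-atom bond-unit motif.  Bond assignment is
    a partition: a ring bond shared by several SSSR rings is assigned to
    the first ring (in perception order) that contains it.
    """
    mol = _parse(smiles)
    motifs: list[Motif] = []
    assigned: set[int] = set()
    ring_info = mol.GetRingInfo()
    for atom_ring, bond_ring in zip(ring_info.AtomRings(), ring_info.BondRings()):
        own_bonds = frozenset(b for b in bond_ring if b not in assigned)
        assigned.update(bond_ring)
        motifs.append(Motif(frozenset(atom_ring), own_bonds, "ring"))
    for bond in mol.GetBonds():
        if bond.GetIdx() in assigned:
            continue
        motifs.append(Motif(
            frozenset((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())),
            frozenset((bond.GetIdx(),)), "bond"))
    if not motifs:  # single heavy atom, no bonds: the atom is its own unit
        motifs.append(Motif(frozenset(range(mol.GetNumAtoms())),
                            frozenset(), "bond"))
    return motifs


def _motifs_adjacent(a: Motif, b: Motif, bond_pairs: set) -> bool:
    if a.atoms & b.atoms:
        return True
    return any((u, v) in bond_pairs or (v, u) in bond_pairs
               for u in a.atoms for v in b.atoms)


def featurize_motif(motif: Motif, mol: Chem.Mol, n_neighbors: int,
                    vocab: FeatureVocabulary | None = None) -> np.ndarray:
    """92-dim feature vector of one motif.

    The symbol block is multi-hot (a motif usually contains several
    element types); count blocks clamp to their last bin.
    """
    vocab = vocab or FeatureVocabulary()
    atoms = [mol.GetAtomWithIdx(i) for i in sorted(motif.atoms)]
    sym = np.zeros(len(vocab.atom_symbols))
    for a in atoms:
        sym[vocab.symbol_index(a.GetSymbol())] = 1.0
    simple_ring = motif.kind == "ring"
    return np.concatenate([
        sym,
        _one_hot(len(atoms), vocab.motif_count_bins),
        _one_hot(n_neighbors, vocab.motif_count_bins),
        _one_hot(sum(a.GetTotalNumHs() for a in atoms), vocab.motif_h_bins),
        _one_hot(sum(a.GetImplicitValence() for a in atoms),
                 vocab.motif_valence_bins),
        [1.0 if simple_ring else 0.0],
        [1.0 if motif.kind == "bond" else 0.0],
    ])


def build_motif_graph(smiles: str,
                      vocab: FeatureVocabulary | None = None) -> MotifGraph:
    """Build the motif-level graph of a molecule from its SMILES."""
    vocab = vocab or FeatureVocabulary()
    mol = _parse(smiles)
    motifs = decompose_motifs(smiles)
    bond_pairs = {(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
                  for b in mol.GetBonds()}
    n = len(motifs)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if _motifs_adjacent(motifs[i], motifs[j], bond_pairs)]
    degree = np.zeros(n, dtype=int)
    for i, j in edges:
        degree[i] += 1
        degree[j] += 1
    # a ring fused to another ring (shared atoms) is not a "simple" ring
    fused = set()
    for i in range(n):
        for j in range(i + 1, n):
            if (motifs[i].kind == motifs[j].kind == "ring"
                    and motifs[i].atoms & motifs[j].atoms):
                fused.update((i, j))
    feats = []
    for i, m in enumerate(motifs):
        row = featurize_motif(m, mol, int(degree[i]), vocab)
        if i in fused:
            row[-2] = 0.0
        feats.append(row)
    return MotifGraph(
        n_nodes=n,
        node_features=np.stack(feats),
        edges=edges,
        motif_atoms=[m.atoms for m in motifs],
        motif_kind=[m.kind for m in motifs],
        smiles=smiles,
    )
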