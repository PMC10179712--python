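"""Atom- and motif-graph construction and featurization."""

import networkx as nx
import numpy as np
import pytest
from rdkit import Chem

from tridta.drug_graphs import (ATOM_FEATURE_DIM, MOTIF_FEATURE_DIM,
                                FeatureVocabulary, SmilesParseError,
                                build_atom_graph, build_motif_graph,
                                decompose_motifs, featurize_atom)


@pytest.mark.parametrize("smiles,n_nodes,n_edges", [
    ("C", 1, 0),                            # methane: single heavy atom
    ("c1ccccc1", 6, 6),                     # benzene
    ("CC(=O)OC1=CC=CC=C1C(=O)O", 13, 13),   # aspirin
    ("CC", 2, 1),
    ("C1CC1", 3, 3),                        # cyclopropane
])
def test_atom_graph_counts(smiles, n_nodes, n_edges):
    g = build_atom_graph(smiles)
    assert g.n_nodes == n_nodes
    assert len(g.edges) == n_edges
    assert g.node_features.shape == (n_nodes, ATOM_FEATURE_DIM)


def test_atom_graph_edges_symmetric_no_self(small_molecules):
    for smi in small_molecules:
        g = build_atom_graph(smi)
        for i, j in g.edges:
            assert i != j
            assert 0 <= i < g.n_nodes and 0 <= j < g.n_nodes
        assert len(set(g.edges)) == len(g.edges)


def test_benzene_aromatic_flags():
    g = build_atom_graph("c1ccccc1")
    assert np.all(g.node_features[:, -1] == 1.0)


def test_atom_feature_row_sums(small_molecules):
    """Four one-hot blocks plus the aromatic flag: rows sum to 4 or 5."""
    for smi in small_molecules:
        g = build_atom_graph(smi)
        sums = g.node_features.sum(axis=1)
        aromatic = g.node_features[:, -1]
        assert np.array_equal(sums, 4.0 + aromatic)


def test_featurize_atom_blocks(vocab):
    mol = Chem.MolFromSmiles("c1ccccc1")
    v = featurize_atom(mol.GetAtomWithIdx(0), vocab)
    assert v.shape == (ATOM_FEATURE_DIM,)
    assert v[vocab.atom_symbols.index("C")] == 1.0
    assert v[44 + 2] == 1.0          # heavy-atom degree 2 in the ring
    assert v[-1] == 1.0              # aromatic
    methane = Chem.MolFromSmiles("C")
    assert featurize_atom(methane.GetAtomWithIdx(0), vocab).sum() == 4.0


def test_unknown_symbol_maps_to_last_slot(vocab):
    mol = Chem.MolFromSmiles("[Te]")
    v = featurize_atom(mol.GetAtomWithIdx(0), vocab)
    assert v[43] == 1.0
    assert v[:43].sum() == 0.0


def test_invalid_smiles_error_names_input():
    with pytest.raises(SmilesParseError, match="not-a-smiles"):
        build_atom_graph("not-a-smiles")


@pytest.mark.parametrize("smiles,expected", [
    ("c1ccccc1", [("ring", 6)]),
    ("CC", [("bond", 2)]),
    ("Cc1ccccc1", [("ring", 6), ("bond", 2)]),
])
def test_decompose_motifs(smiles, expected):
    motifs = decompose_motifs(smiles)
    got = sorted((m.kind, len(m.atoms)) for m in motifs)
    assert got == sorted(expected)


def test_motif_bond_partition(small_molecules):
    """Every molecular bond is assigned to exactly one motif."""
    for smi in small_molecules:
        mol = Chem.MolFromSmiles(smi)
        motifs = decompose_motifs(smi)
        all_bonds = [b for m in motifs for b in m.bonds]
        assert sorted(all_bonds) == list(range(mol.GetNumBonds()))
        covered_atoms = set().union(*(m.atoms for m in motifs))
        assert covered_atoms == set(range(mol.GetNumAtoms()))


@pytest.mark.parametrize("smiles,n_nodes,n_edges", [
    ("c1ccccc1", 1, 0),
    ("Cc1ccccc1", 2, 1),
    ("c1ccc2ccccc2c1", 2, 1),    # naphthalene: two fused SSSR rings
])
def test_motif_graph_examples(smiles, n_nodes, n_edges):
    g = build_motif_graph(smiles)
    assert g.n_nodes == n_nodes
    assert len(g.edges) == n_edges
    assert g.node_features.shape == (n_nodes, MOTIF_FEATURE_DIM)


def test_acyclic_motif_graph_is_line_graph(small_molecules):
    """Without rings, motifs are the bonds: the motif graph is the line
    graph of the atom graph."""
    for smi in small_molecules:
        mol = Chem.MolFromSmiles(smi)
        if mol.GetRingInfo().NumRings() or mol.GetNumBonds() == 0:
            continue
        atom_g = build_atom_graph(smi)
        motif_g = build_motif_graph(smi)
        assert motif_g.n_nodes == mol.GetNumBonds()
        G = nx.Graph(atom_g.edges)
        G.add_nodes_from(range(atom_g.n_nodes))
        L = nx.line_graph(G)
        M = nx.Graph(motif_g.edges)
        M.add_nodes_from(range(motif_g.n_nodes))
        assert nx.is_isomorphic(L, M)


def test_motif_features_benzene_and_ethane():
    ring = build_motif_graph("c1ccccc1").node_features[0]
    assert ring[:44].sum() == 1.0        # only carbon present
    assert ring[-2] == 1.0 and ring[-1] == 0.0
    bond = build_motif_graph("CC").node_features[0]
    assert bond[-2] == 0.0 and bond[-1] == 1.0
    assert bond[44 + 2] == 1.0           # atom-count one-hot at 2


def test_fused_rings_not_simple():
    g = build_motif_graph("c1ccc2ccccc2c1")
    assert np.all(g.node_features[:, -2] == 0.0)   # fused: not simple rings
    assert [k for k in g.motif_kind] == ["ring", "ring"]


def test_feature_determinism(small_molecules):
    for smi in small_molecules:
        a1, a2 = build_atom_graph(smi), build_atom_graph(smi)
        m1, m2 = build_motif_graph(smi), build_motif_graph(smi)
        assert np.array_equal(a1.node_features, a2.node_features)
        assert a1.edges == a2.edges
        assert np.array_equal(m1.node_features, m2.node_features)
        assert m1.edges == m2.edges


def test_atom_edge_count_matches_bond_count(small_molecules):
    for smi in small_molecules:
        g = build_atom_graph(smi)
        assert len(g.edges) == Chem.MolFromSmiles(smi).GetNumBonds()


def test_json_round_trip():
    g = build_atom_graph("Cc1ccccc1")
    g2 = type(g).from_json(g.to_json())
    assert np.array_equal(g.node_features, g2.node_features)
    assert g.edges == g2.edges
    m = build_motif_graph("Cc1ccccc1")
    m2 = type(m).from_json(m.to_json())
    assert np.array_equal(m.node_features, m2.node_features)
    assert m.motif_atoms == m2.motif_atoms
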