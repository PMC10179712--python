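"""Contact-map splicing, thresholding and residue featurization."""

import numpy as np
import pytest

from tridta.protein_graphs import (AMINO_ALPHABET, RESIDUE_FEATURE_DIM,
                                   ContactMap, PredictorContractError,
                                   SequenceError, featurize_residue,
                                   splice_contact_map, threshold_graph)
from tridta.synthetic import stub_contact_predictor


def _random_sequence(rng, length):
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return "".join(letters[rng.integers(0, 20, size=length)])


def _oracle_splice(sequence, predictor, windowsize=500):
    """Independent paste-and-average assembly of the windowed map."""
    L = len(sequence)
    w = windowsize
    starts = []
    s = 0
    while s + 2 * w <= L:
        starts.append(s)
        s += w
    if starts[-1] + 2 * w < L:
        starts.append(L - 2 * w)
    accum = np.zeros((L, L))
    count = np.zeros((L, L))
    for s in starts:
        accum[s:s + 2 * w, s:s + 2 * w] += predictor(sequence[s:s + 2 * w])
        count[s:s + 2 * w, s:s + 2 * w] += 1
    out = np.zeros((L, L))
    np.divide(accum, count, out=out, where=count > 0)
    return out


def test_short_sequence_is_direct_call():
    rng = np.random.default_rng(0)
    seq = _random_sequence(rng, 800)
    pred = stub_contact_predictor("hash")
    cmap = splice_contact_map(seq, pred)
    assert np.array_equal(cmap.matrix, pred(seq))


def test_constant_stub_average_is_idempotent():
    rng = np.random.default_rng(1)
    seq = _random_sequence(rng, 1500)
    cmap = splice_contact_map(seq, stub_contact_predictor("constant",
                                                          value=0.7))
    covered = cmap.matrix > 0
    assert np.allclose(cmap.matrix[covered], 0.7)
    # cells farther apart than the window width are an inherent blind spot
    i, j = 0, 1400
    assert cmap.matrix[i, j] == 0.0


def test_splice_matches_oracle_on_window_dependent_stub():
    rng = np.random.default_rng(2)
    pred = stub_contact_predictor("hash")
    for length in (1200, 1501, 2047):
        seq = _random_sequence(rng, length)
        got = splice_contact_map(seq, pred).matrix
        want = _oracle_splice(seq, pred)
        assert np.allclose(got, want)


def test_splice_preserves_symmetry():
    rng = np.random.default_rng(3)
    seq = _random_sequence(rng, 1300)
    m = splice_contact_map(seq, stub_contact_predictor("hash")).matrix
    assert np.allclose(m, m.T)


@pytest.mark.parametrize("length", [1001, 1499, 1500, 2000, 2750, 3999])
def test_window_band_fully_covered(length):
    """Every pair closer than windowsize lies inside at least one window."""
    w = 500
    starts = []
    s = 0
    while s + 2 * w <= length:
        starts.append(s)
        s += w
    if starts[-1] + 2 * w < length:
        starts.append(length - 2 * w)
    starts = np.asarray(starts)
    for d in range(w):
        lo = np.arange(0, length - d)         # pair (lo, lo+d)
        k = np.searchsorted(starts, lo, side="right") - 1
        ok = (k >= 0) & (starts[np.clip(k, 0, None)] + 2 * w > lo + d)
        assert ok.all(), f"length {length}, separation {d}"


def test_threshold_all_zero():
    g = threshold_graph(ContactMap(np.zeros((10, 10)), "A" * 10))
    assert g.n_nodes == 10 and len(g.edges) == 0


def test_threshold_single_entry():
    m = np.zeros((8, 8))
    m[2, 5] = m[5, 2] = 0.7
    g = threshold_graph(ContactMap(m, "ACDEFGHI"))
    assert g.edges == [(2, 5)]
    assert np.allclose(g.edge_weights, [0.7])


def test_threshold_matches_brute_force_count():
    rng = np.random.default_rng(4)
    for _ in range(5):
        L = int(rng.integers(5, 60))
        m = rng.random((L, L))
        m = (m + m.T) / 2
        g = threshold_graph(ContactMap(m, "A" * L))
        brute = sum(1 for i in range(L) for j in range(i + 1, L)
                    if m[i, j] >= 0.5)
        assert len(g.edges) == brute


def test_threshold_monotone():
    rng = np.random.default_rng(5)
    m = rng.random((40, 40))
    m = (m + m.T) / 2
    cmap = ContactMap(m, "A" * 40)
    counts = [len(threshold_graph(cmap, threshold=t).edges)
              for t in (0.3, 0.5, 0.7, 0.9)]
    assert counts == sorted(counts, reverse=True)


def test_residue_features():
    for letter in AMINO_ALPHABET:
        v = featurize_residue(letter)
        assert v.shape == (RESIDUE_FEATURE_DIM,)
        assert v[:25].sum() == 1.0                  # one-hot block
        assert np.all((v[25:] >= 0) & (v[25:] <= 1.0 + 1e-12))
    assert not np.array_equal(featurize_residue("G"), featurize_residue("A"))
    with pytest.raises(SequenceError):
        featurize_residue("J")


def test_sequence_validation_and_contract():
    with pytest.raises(SequenceError):
        splice_contact_map("ACDJ", stub_contact_predictor("constant"))
    with pytest.raises(PredictorContractError):
        splice_contact_map("ACDE", lambda s: np.zeros((2, 2)))
    with pytest.raises(PredictorContractError):
        splice_contact_map("ACDE", lambda s: np.full((4, 4), 2.0))
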