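"""Weighted residue-contact graphs for proteins of arbitrary length.

A contact predictor (any callable mapping a sequence of length L <= 1024
to a symmetric LxL matrix of contact probabilities) supplies the raw
contact map.  Sequences longer than 1000 residues exceed the predictor's
context, so the map is assembled from sliding windows of width
2*windowsize (default 1000) advanced by windowsize along the diagonal;
cells covered by more than one window hold the mean of the window
predictions and cells outside every window stay 0.  Thresholding the map
at 0.5 yields the weighted protein graph: residues as nodes, retained
contacts as edges weighted by their probability.

Residue node features are 33-dimensional: one-hot residue type over the
25-letter amino-acid alphabet (20 standard residues plus B, Z, U, O, X),
five binary class flags (aromatic, aliphatic, polar-neutral, acidic,
basic) and three physicochemical scalars (molecular weight, Kyte-
Doolittle hydropathy, side-chain pKa) each min-max rescaled to [0, 1].
Ambiguity codes carry zero class flags and midpoint scalars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

RESIDUE_FEATURE_DIM = 33
AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZUOX"  # 25 letters

ContactPredictor = Callable[[str], np.ndarray]


class SequenceError(ValueError):
    """Raised for sequences containing letters outside the alphabet."""


class PredictorContractError(ValueError):
    """Raised when a contact predictor violates its output contract."""


# residue -> (aromatic, aliphatic, polar-neutral, acidic, basic,
#             molecular weight Da, Kyte-Doolittle hydropathy, side-chain pKa)
# pKa of residues without an ionizable side chain is recorded as 7.0
# (neutral placeholder) so the scalar block stays total.
_RESIDUE_TABLE = {
    "A": (0, 1, 0, 0, 0,  89.09,  1.8, 7.00),
    "C": (0, 0, 1, 0, 0, 121.16,  2.5, 8.18),
    "D": (0, 0, 0, 1, 0, 133.10, -3.5, 3.65),
    "E": (0, 0, 0, 1, 0, 147.13, -3.5, 4.25),
    "F": (1, 0, 0, 0, 0, 165.19,  2.8, 7.00),
    "G": (0, 1, 0, 0, 0,  75.07, -0.4, 7.00),
    "H": (1, 0, 0, 0, 1, 155.16, -3.2, 6.00),
    "I": (0, 1, 0, 0, 0, 131.17,  4.5, 7.00),
    "K": (0, 0, 0, 0, 1, 146.19, -3.9, 10.53),
    "L": (0, 1, 0, 0, 0, 131.17,  3.8, 7.00),
    "M": (0, 0, 0, 0, 0, 149.21,  1.9, 7.00),
    "N": (0, 0, 1, 0, 0, 132.12, -3.5, 7.00),
    "P": (0, 0, 0, 0, 0, 115.13, -1.6, 7.00),
    "Q": (0, 0, 1, 0, 0, 146.15, -3.5, 7.00),
    "R": (0, 0, 0, 0, 1, 174.20, -4.5, 12.48),
    "S": (0, 0, 1, 0, 0, 105.09, -0.8, 7.00),
    "T": (0, 0, 1, 0, 0, 119.12, -0.7, 7.00),
    "V": (0, 1, 0, 0, 0, 117.15,  4.2, 7.00),
    "W": (1, 0, 0, 0, 0, 204.23, -0.9, 7.00),
    "Y": (1, 0, 1, 0, 0, 181.19, -1.3, 10.07),
    # ambiguity / rare codes: no class flags, midpoint-ish scalars
    "B": (0, 0, 0, 0, 0, 132.61, -3.5, 5.00),
    "Z": (0, 0, 0, 0, 0, 146.64, -3.5, 5.50),
    "U": (0, 0, 1, 0, 0, 168.05,  2.5, 5.43),
    "O": (0, 0, 0, 0, 1, 255.31, -3.9, 9.70),
    "X": (0, 0, 0, 0, 0, 136.90,  0.0, 7.00),
}

_MW = np.array([_RESIDUE_TABLE[a][5] for a in AMINO_ALPHABET])
_HYDRO = np.array([_RESIDUE_TABLE[a][6] for a in AMINO_ALPHABET])
_PKA = np.array([_RESIDUE_TABLE[a][7] for a in AMINO_ALPHABET])


def _rescale(value: float, arr: np.ndarray) -> float:
    return float((value - arr.min()) / (arr.max() - arr.min()))


@dataclass
class ContactMap:
    """Residue-residue contact probabilities of one sequence."""

    matrix: np.ndarray
    sequence: str

    def __post_init__(self):
        L = len(self.sequence)
        if self.matrix.shape != (L, L):
            raise ValueError("contact map shape must match sequence length")


@dataclass
class WeightedProteinGraph:
    """Thresholded contact graph: residues as nodes, contacts as edges."""

    n_nodes: int
    node_features: np.ndarray          # (n_nodes, 33)
    edges: list                        # unordered pairs (i, j), i < j
    edge_weights: np.ndarray           # probability per edge
    sequence: str


def validate_sequence(sequence: str) -> str:
    sequence = sequence.strip().upper()
    bad = set(sequence) - set(AMINO_ALPHABET)
    if bad:
        raise SequenceError(
            f"sequence contains letters outside the 25-letter alphabet: "
            f"{sorted(bad)}")
    return sequence


def featurize_residue(letter: str) -> np.ndarray:
    """33-dim feature vector of one residue letter."""
    letter = letter.upper()
    if letter not in _RESIDUE_TABLE:
        raise SequenceError(f"unknown amino-acid letter {letter!r}")
    row = _RESIDUE_TABLE[letter]
    one_hot = np.zeros(len(AMINO_ALPHABET))
    one_hot[AMINO_ALPHABET.index(letter)] = 1.0
    return np.concatenate([
        one_hot,
        np.asarray(row[:5], dtype=float),
        [_rescale(row[5], _MW), _rescale(row[6], _HYDRO),
         _rescale(row[7], _PKA)],
    ])


def _call_predictor(predictor: ContactPredictor, seq: str) -> np.ndarray:
    out = np.asarray(predictor(seq), dtype=float)
    if out.shape != (len(seq), len(seq)):
        raise PredictorContractError(
            f"predictor returned shape {out.shape} for a length-{len(seq)} "
            "sequence")
    if out.min() < 0.0 or out.max() > 1.0:
        raise PredictorContractError("predictor values must lie in [0, 1]")
    return out


def splice_contact_map(sequence: str, predictor: ContactPredictor,
                       windowsize: int = 500,
                       max_direct: int = 1000) -> ContactMap:
    """Assemble a full contact map, windowing sequences beyond the cap.

    Sequences of length <= ``max_direct`` are predicted in one call.
    Longer ones are covered by windows ``[k*w, k*w + 2w)`` for
    k = 0, 1, ... plus, if the last regular window stops short, a final
    window anchored at ``L - 2w``; overlap cells average the predictions
    that cover them.  Pairs farther apart than the window width are an
    inherent blind spot of the scheme and stay 0.
    """
    sequence = validate_sequence(sequence)
    L = len(sequence)
    if L < 2:
        raise SequenceError("sequence must have length >= 2")
    if L <= max_direct:
        return ContactMap(_call_predictor(predictor, sequence), sequence)

    w = windowsize
    starts = list(range(0, L - 2 * w + 1, w))
    if starts[-1] + 2 * w < L:
        starts.append(L - 2 * w)
    accum = np.zeros((L, L))
    count = np.zeros((L, L))
    for s in starts:
        e = s + 2 * w
        block = _call_predictor(predictor, sequence[s:e])
        accum[s:e, s:e] += block
        count[s:e, s:e] += 1.0
    covered = count > 0
    accum[covered] /= count[covered]
    return ContactMap(accum, sequence)


def threshold_graph(cmap: ContactMap,
                    threshold: float = 0.5) -> WeightedProteinGraph:
    """Weighted protein graph from a contact map.

    An edge (i, j), i < j, exists iff the contact probability is at least
    ``threshold`` (ties retained); its weight is that probability.
    Residues without any retained contact remain as isolated nodes.
    """
    seq = cmap.sequence
    iu, ju = np.triu_indices(len(seq), k=1)
    vals = cmap.matrix[iu, ju]
    keep = vals >= threshold
    features = np.stack([featurize_residue(a) for a in seq])
    return WeightedProteinGraph(
        n_nodes=len(seq),
        node_features=features,
        edges=list(zip(iu[keep].tolist(), ju[keep].tolist())),
        edge_weights=vals[keep].copy(),
        sequence=seq,
    )


def build_protein_graph(sequence: str, predictor: ContactPredictor,
                        threshold: float = 0.5,
                        windowsize: int = 500) -> WeightedProteinGraph:
    """Convenience wrapper: predict/splice the map, then threshold it."""
    return threshold_graph(
        splice_contact_map(sequence, predictor, windowsize=windowsize),
        threshold=threshold)
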