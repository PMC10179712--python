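"""Dataset parsing, the Kd -> pKd transform, and train/test splitting.

The canonical on-disk format is a long-format table with one row per
measured drug-protein pair and columns ``drug_id, smiles, protein_id,
sequence, affinity``.  Davis-style dissociation constants in nanomolar
are mapped to the pKd scale with pKd = -log10(Kd / 1e9); a Kd of
10,000 nM gives the boundary value 5.0 used for undetected binders.
Splits follow the benchmark convention of shuffling into n equal parts
(sizes within one of each other) with one part held out for testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from rdkit import Chem

from .protein_graphs import SequenceError, validate_sequence

REQUIRED_COLUMNS = ("drug_id", "smiles", "protein_id", "sequence", "affinity")


class DataError(ValueError):
    """Raised for malformed affinity tables."""


@dataclass(frozen=True)
class DTARecord:
    """One measured drug-protein pair: the unit of training data."""

    drug_id: str
    smiles: str
    protein_id: str
    sequence: str
    affinity: float

    def __post_init__(self):
        if not self.drug_id or not self.protein_id:
            raise DataError("record ids must be non-empty")
        if not math.isfinite(self.affinity):
            raise DataError(
                f"affinity of pair ({self.drug_id}, {self.protein_id}) "
                "is not finite")


@dataclass
class DatasetSplit:
    """Fold assignment per record; one fold is the held-out test part."""

    assignments: np.ndarray     # fold index per record
    n_parts: int
    seed: int
    test_part: int = 0

    def train_indices(self) -> np.ndarray:
        return np.flatnonzero(self.assignments != self.test_part)

    def test_indices(self) -> np.ndarray:
        return np.flatnonzero(self.assignments == self.test_part)

    def to_json(self) -> str:
        return json.dumps({
            "assignments": self.assignments.tolist(),
            "n_parts": self.n_parts,
            "seed": self.seed,
            "test_part": self.test_part,
        })

    @classmethod
    def from_json(cls, s: str) -> "DatasetSplit":
        d = json.loads(s)
        return cls(assignments=np.asarray(d["assignments"], dtype=int),
                   n_parts=d["n_parts"], seed=d["seed"],
                   test_part=d["test_part"])


def kd_to_pkd(kd: float) -> float:
    """pKd = -log10(Kd / 1e9) for a dissociation constant Kd in nM."""
    if kd <= 0:
        raise DataError(f"Kd must be positive, got {kd}")
    return -math.log10(kd / 1e9)


def load_long_table(path) -> list[DTARecord]:
    """Read and validate a long-format affinity table (TSV or CSV).

    Every SMILES must parse, every sequence must stay inside the
    25-letter alphabet, and (drug, protein) pairs must be unique; any
    violation is reported with its row number.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise DataError(f"empty file: {path}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise DataError(f"{path}: no data rows")
    records = []
    seen = {}
    for row_idx, row in enumerate(df.itertuples(index=False)):
        pair = (row.drug_id, row.protein_id)
        if pair in seen:
            raise DataError(
                f"{path}: duplicate pair {pair} at rows {seen[pair]} and "
                f"{row_idx}")
        seen[pair] = row_idx
        if Chem.MolFromSmiles(row.smiles) is None:
            raise DataError(f"{path}: invalid SMILES at row {row_idx}: "
                            f"{row.smiles!r}")
        try:
            seq = validate_sequence(row.sequence)
        except SequenceError as exc:
            raise DataError(f"{path}: row {row_idx}: {exc}") from exc
        try:
            affinity = float(row.affinity)
        except ValueError:
            raise DataError(f"{path}: non-numeric affinity at row {row_idx}")
        records.append(DTARecord(row.drug_id, row.smiles, row.protein_id,
                                 seq, affinity))
    return records


def save_long_table(records, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    pd.DataFrame([{
        "drug_id": r.drug_id, "smiles": r.smiles,
        "protein_id": r.protein_id, "sequence": r.sequence,
        "affinity": r.affinity,
    } for r in records]).to_csv(path, sep=sep, index=False)


def make_split(records, n_parts: int = 6, seed: int = 0,
               test_part: int = 0) -> DatasetSplit:
    """Seeded shuffle into ``n_parts`` folds of size within one of each
    other; fold ``test_part`` is the held-out test set."""
    n = len(records)
    if n < n_parts:
        raise DataError(f"cannot split {n} records into {n_parts} parts")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    assignments[perm] = np.arange(n) % n_parts
    return DatasetSplit(assignments, n_parts, seed, test_part)


def records_from_matrix(affinity: pd.DataFrame, smiles_by_drug: dict,
                        sequence_by_protein: dict,
                        transform_kd: bool = False) -> list[DTARecord]:
    """Adapter for the published drug x protein matrix layout.

    ``affinity`` is indexed by drug id with protein ids as columns; NaN
    cells (unmeasured pairs) are skipped.  With ``transform_kd`` the cell
    values are treated as Kd in nM and mapped to pKd.
    """
    records = []
    for drug_id in affinity.index:
        for protein_id in affinity.columns:
            value = affinity.loc[drug_id, protein_id]
            if pd.isna(value):
                continue
            value = kd_to_pkd(float(value)) if transform_kd else float(value)
            records.append(DTARecord(
                str(drug_id), smiles_by_drug[str(drug_id)],
                str(protein_id), sequence_by_protein[str(protein_id)],
                value))
    return records


def read_fasta(path) -> dict:
    """Sequences keyed by FASTA record id."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="")
         for name, seq in sequences.items()],
        str(path), "fasta")
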