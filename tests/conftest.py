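import numpy as np
import pytest

from tridta.drug_graphs import FeatureVocabulary
from tridta.synthetic import SyntheticConfig, gen_dataset, stub_contact_predictor
from tridta.train import prepare_graphs


@pytest.fixture(scope="session")
def vocab():
    return FeatureVocabulary()


@pytest.fixture(scope="session")
def small_molecules():
    # hand-picked SMILES spanning rings, chains, fused systems, heteroatoms
    return [
        "C", "CC", "CCO", "c1ccccc1", "Cc1ccccc1", "c1ccc2ccccc2c1",
        "CC(=O)OC1=CC=CC=C1C(=O)O", "C1CCNCC1", "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
        "OC(=O)c1ccccc1O", "C1CC1", "N#Cc1ccccc1",
    ]


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Small synthetic dataset with short proteins for fast unit tests."""
    cfg = SyntheticConfig(n_drugs=6, n_proteins=4, n_pairs=16,
                          seq_len_range=(40, 120), noise_sd=0.1, seed=7)
    records, sequences, manifest = gen_dataset(cfg)
    return records, sequences, manifest


@pytest.fixture(scope="session")
def synthetic_cache(synthetic_dataset):
    records, _, _ = synthetic_dataset
    return prepare_graphs(records, stub_contact_predictor("banded"))
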