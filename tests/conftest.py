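import numpy as np
import pytest

from profusenet.sequence_io import LabeledDataset, ProteinSequence
from profusenet.synthetic_data import GeneratorConfig, default_motifs, generate_dataset

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_dataset(rng) -> LabeledDataset:
    """12 random labeled sequences, 6 per class."""
    seqs = []
    for i in range(6):
        seqs.append(ProteinSequence(f"P{i}", random_protein(rng, 40), "CML"))
        seqs.append(ProteinSequence(f"N{i}", random_protein(rng, 40), "Control"))
    return LabeledDataset(seqs)


@pytest.fixture(scope="session")
def easy_corpus():
    """Small, perfectly separable planted-motif corpus for pipeline tests."""
    cfg = GeneratorConfig(
        n_total=80,
        length_range=(40, 70),
        motifs=default_motifs(insert_prob=1.0, substitution_rate=0.0),
        seed=7,
    )
    return generate_dataset(cfg)
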