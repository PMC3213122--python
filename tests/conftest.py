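import numpy as np
import pytest

from dmfs import DNA, PROTEIN, Dataset, LabeledSequence


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    symbols = "ACGTN" if with_n else "ACGT"
    p = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(symbols), size=length, p=p))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(PROTEIN.symbols), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def tiny_dna_dataset():
    seqs = [
        LabeledSequence("p1", "ACGTACGTAA", 1),
        LabeledSequence("p2", "ACGTTTTTGG", 1),
        LabeledSequence("p3", "CCACGTACCA", 1),
        LabeledSequence("n1", "GGGGGCCCCC", 0),
        LabeledSequence("n2", "GCGCGCGCGC", 0),
        LabeledSequence("n3", "TGCATGCAGG", 0),
    ]
    return Dataset(seqs, DNA)
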