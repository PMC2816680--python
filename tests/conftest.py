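import numpy as np
import pytest

from fiveprime.folding import get_backend
from fiveprime.genome_io import CodingSequence
from fiveprime.shuffling import standard_code
from fiveprime.synthetic_data import SyntheticGenomeConfig, generate_genome


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture()
def simple_backend():
    return get_backend("simple-nn")


@pytest.fixture(scope="session")
def small_genome():
    """A small synthetic gene set shared by read-only tests."""
    cfg = SyntheticGenomeConfig(n_genes=30, seed=42, length_codons=(55, 90))
    genes, truth = generate_genome(cfg)
    return genes, truth


def make_gene(seq: str, gene_id: str = "g1", species_id: str = "sp") -> CodingSequence:
    return CodingSequence(gene_id, species_id, seq)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
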