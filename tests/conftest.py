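import numpy as np
import pytest

from codoncomp.genetic_code import ALL_CODONS, sense_codons
from codoncomp.io import CodonCountTable


@pytest.fixture
def cgcgcg_table() -> CodonCountTable:
    """Codon table of the dinucleotide-repeat sequence CGCGCG (CGC + GCG)."""
    return CodonCountTable(label="cgcgcg", counts={"CGC": 1, "GCG": 1})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def make_random_table(rng: np.random.Generator, label: str = "rand", max_count: int = 5) -> CodonCountTable:
    """Small random integer table guaranteed to have sense-codon counts."""
    counts = {c: int(rng.integers(0, max_count + 1)) for c in ALL_CODONS}
    if sum(counts[c] for c in sense_codons()) == 0:
        counts["ATG"] = 1
    return CodonCountTable(label=label, counts=counts, n_cds=10)


def random_positional_freqs(rng: np.random.Generator) -> list[dict[str, float]]:
    """Three random nucleotide-frequency scopes (Dirichlet, strictly positive)."""
    return [
        dict(zip("ACGT", rng.dirichlet(np.ones(4)))) for _ in range(3)
    ]
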