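import numpy as np
import pytest

from codonbalance.genetic_code import SENSE_CODONS, CodonTable, Gene, GeneSet


@pytest.fixture(scope="session")
def table() -> CodonTable:
    return CodonTable.standard()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


def random_genes(
    rng: np.random.Generator,
    n: int = 50,
    length: tuple[int, int] = (30, 120),
    with_expression: bool = True,
) -> GeneSet:
    """Quick unstructured gene set (uniform over the 61 sense codons)."""
    genes = []
    for i in range(n):
        ln = int(rng.integers(*length))
        codons = tuple(rng.choice(SENSE_CODONS, size=ln))
        kwargs = {}
        if with_expression:
            kwargs["mrna"] = float(rng.lognormal(1.0, 1.0))
            kwargs["protein"] = float(rng.lognormal(6.0, 1.0))
        genes.append(Gene(id=f"r{i:03d}", codons=codons, **kwargs))
    return GeneSet(genes)


@pytest.fixture()
def genes50(rng) -> GeneSet:
    return random_genes(rng, n=50)
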