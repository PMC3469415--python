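import numpy as np
import pandas as pd
import pytest

from pleionet.io import GenotypeMatrix, PhenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_genotypes():
    return GenotypeMatrix(pd.DataFrame(
        [[0, 1], [1, 0], [1, 1], [0, 0]],
        index=["s1", "s2", "s3", "s4"], columns=["locA", "locB"],
        dtype=float,
    ))


@pytest.fixture
def small_phenotypes():
    return PhenotypeTable(pd.DataFrame(
        {"me": [0.1, 1.2, -0.3, 0.9], "pr": [1.0, 0.2, 0.4, -0.5]},
        index=["s1", "s2", "s3", "s4"],
    ))


def random_dataset(rng, n=200, loci=4, phenotypes=2):
    """Unstructured random genotype/phenotype pair for algebraic tests."""
    G = GenotypeMatrix(pd.DataFrame(
        (rng.random((n, loci)) < 0.5).astype(float),
        index=[f"s{i}" for i in range(n)],
        columns=[f"L{j + 1}" for j in range(loci)],
    ))
    Y = PhenotypeTable(pd.DataFrame(
        rng.normal(size=(n, phenotypes)),
        index=G.sample_ids,
        columns=[f"P{m + 1}" for m in range(phenotypes)],
    ))
    return G, Y
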