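import numpy as np
import pytest

from abcne import GenotypeMatrix


def matrix_from_strings(rows, **kwargs):
    """Build a GenotypeMatrix from genotype strings like "12" or "00"."""
    calls = [[(int(g[0]), int(g[1])) for g in row] for row in rows]
    return GenotypeMatrix(np.array(calls, dtype=np.int8), **kwargs)


def random_matrix(rng, n_ind, n_loci, missing_rate=0.0):
    """Random biallelic matrix, each allele 1/2 iid, optional missingness."""
    calls = rng.integers(1, 3, size=(n_ind, n_loci, 2)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n_ind, n_loci)) < missing_rate
        calls[mask] = 0
    return GenotypeMatrix(calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240712)


@pytest.fixture
def hwe_matrix():
    """One locus with genotype counts 1x(11), 2x(12), 1x(22): exact HWE at p=0.5."""
    return matrix_from_strings([["11"], ["12"], ["12"], ["22"]])
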