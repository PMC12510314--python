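import numpy as np
import pytest

from seedvigor.popgen import HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_pop_matrix(rng):
    """20 + 20 haplotypes, 40 segregating sites over ~9 kb, panmictic."""
    n, s = 40, 40
    freqs = rng.uniform(0.1, 0.9, s)
    alleles = (rng.random((n, s)) < freqs).astype(np.int8)
    positions = np.sort(rng.choice(np.arange(1, 9001), size=s, replace=False))
    labels = np.array(["teosinte"] * 20 + ["maize"] * 20)
    return HaplotypeMatrix(alleles, positions, labels, contig="chr4")
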