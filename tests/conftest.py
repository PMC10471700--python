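import numpy as np
import pytest

from fibroprog.genome import GeneModel, GenomeSpec


@pytest.fixture
def genome():
    return GenomeSpec({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def gene_plus():
    return GeneModel("gplus", "chr1", 10_000, 20_000, "+")


@pytest.fixture
def gene_minus():
    return GeneModel("gminus", "chr1", 50_000, 60_000, "-")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
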