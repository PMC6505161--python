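import numpy as np
import pytest

from bulkblup import founders as qfound


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_map():
    """Two chromosomes of 100 cM with 20 deterministic marker positions."""
    pos = np.tile(np.linspace(0.0, 100.0, 10), 2)
    chrom = np.repeat([1, 2], 10)
    ids = np.array([f"M{i:02d}" for i in range(20)], dtype=object)
    return qfound.GeneticMap(marker_id=ids, chromosome=chrom, position_cM=pos)


@pytest.fixture
def two_locus_map():
    """Single chromosome with two loci 50 cM apart."""
    return qfound.GeneticMap(
        marker_id=np.array(["A", "B"], dtype=object),
        chromosome=np.array([1, 1]),
        position_cM=np.array([0.0, 50.0]),
    )
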