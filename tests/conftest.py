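import numpy as np
import pytest

from chromkit.genome_io import GenomeModel, GenomicInterval, IntervalSet


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_genome():
    """Two small chromosomes, a handful of genes on both strands."""
    genes = IntervalSet(
        [
            GenomicInterval("chr1", 1000, 2000, "+", "gA"),
            GenomicInterval("chr1", 4000, 5500, "-", "gB"),
            GenomicInterval("chr1", 7000, 7800, "+", "gC"),
            GenomicInterval("chr2", 500, 1500, "-", "gD"),
            GenomicInterval("chr2", 3000, 4200, "+", "gE"),
        ],
        label="genes",
    )
    return GenomeModel(chrom_sizes={"chr1": 10_000, "chr2": 6_000}, genes=genes)


def random_interval_set(rng, n, chroms=("chr1", "chr2"), size=10_000, max_len=300):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, size - length))
        out.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(out)
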