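import numpy as np
import pytest

from tripnseq import (
    FragmentSet,
    GenomeModel,
    GenomicInterval,
)


@pytest.fixture
def toy_genome():
    """Two small chromosomes with explicit sequence."""
    rng = np.random.Generator(np.random.PCG64(11))
    bases = np.array(list("ACGT"))
    seqs = {
        "chr1": "".join(rng.choice(bases, size=20_000)),
        "chr2": "".join(rng.choice(bases, size=10_000)),
    }
    return GenomeModel({c: len(s) for c, s in seqs.items()}, seqs)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))


def make_fragments(intervals, sample_id="s1", condition="BrdU+", replicate=0):
    return FragmentSet(
        sample_id,
        condition,
        replicate,
        np.array([iv[0] for iv in intervals]),
        np.array([iv[1] for iv in intervals]),
        np.array([iv[2] for iv in intervals]),
    )


def random_intervals(rng, n, chroms=("chr1",), max_pos=10_000, max_len=500):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out
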