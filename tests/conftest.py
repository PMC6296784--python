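import numpy as np
import pytest

from rloopkit import GeneRecord, GenomicInterval, IntervalSet


def make_interval(chrom="chr1", start=0, end=10):
    return GenomicInterval(chrom, start, end)


def random_intervals(rng, n, n_chroms=3, chrom_length=100_000, max_len=500):
    out = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, chrom_length - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def make_genes(expressions, chrom="chr1", length=100, gap=50):
    """Non-overlapping genes g000, g001, ... with the given expression levels."""
    genes = []
    pos = 0
    for i, e in enumerate(expressions):
        genes.append(
            GeneRecord(f"g{i:03d}", GenomicInterval(chrom, pos, pos + length), float(e))
        )
        pos += length + gap
    return genes


def brute_force_overlaps_any(query, targets):
    return any(
        q.chrom == t.chrom and max(q.start, t.start) < min(q.end, t.end)
        for t in targets
        for q in [query]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
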