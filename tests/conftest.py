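import numpy as np
import pytest

from mobilome_trap.core_io import AlignmentRecord, GenomicInterval
from mobilome_trap.synthetic import random_element, simulate_genome


@pytest.fixture(scope="session")
def small_genome():
    return simulate_genome(2, 100_000, 0.5, seed=101)


@pytest.fixture(scope="session")
def ltr_element():
    return random_element("elem", 4000, "LTR", 300, snp_rate=0.004, seed=202)


def make_record(i, chrom, start, length, strand, sequence=None):
    return AlignmentRecord(
        read_id=f"r{i}",
        interval=GenomicInterval(chrom, start, start + length, strand),
        read_length=length,
        sequence=sequence,
    )


def random_records(rng, n, chrom="locus", span=3000, lengths=(23, 33)):
    """Random ungapped placements for oracle comparisons."""
    out = []
    for i in range(n):
        length = int(rng.integers(lengths[0], lengths[1] + 1))
        start = int(rng.integers(0, span - length))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(make_record(i, chrom, start, length, strand))
    return out
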