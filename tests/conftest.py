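import numpy as np
import pytest

from hcdscan import GenomeLayout, GenomicInterval


@pytest.fixture
def tiny_layout():
    """Two short arms on one chromosome plus a single-arm chromosome."""
    return GenomeLayout([("chr1p", "chr1", 5_000),
                         ("chr1q", "chr1", 3_000),
                         ("chr2", "chr2", 10_000)], bin_size=1_000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_intervals(rng, layout, n, scored=False, max_len=None):
    """Random layout-bound intervals (helper, not a fixture)."""
    out = []
    arms = layout.chrom_arms
    for _ in range(n):
        arm_id, chrom, length = arms[rng.integers(len(arms))]
        off = layout.arm_offset(arm_id)
        lo = int(rng.integers(0, length - 1))
        hi_max = length if max_len is None else min(length, lo + max_len)
        hi = int(rng.integers(lo + 1, hi_max + 1))
        score = float(rng.integers(1, 10)) if scored else None
        out.append(GenomicInterval(chrom, off + lo, off + hi, score=score))
    return out
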