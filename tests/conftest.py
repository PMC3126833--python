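import numpy as np
import pytest

from pansort.snp_calling import Read, ReadPileup


def make_read(start: int, bases: str, qual: int = 30, strand: str = "+",
              read_quality: float = 30.0,
              qualities: tuple[int, ...] | None = None) -> Read:
    if qualities is None:
        n_real = sum(1 for b in bases if b != "-")
        qualities = (qual,) * n_real
    return Read(start=start, strand=strand, bases=bases,
                qualities=qualities, read_quality=read_quality)


def stacked_pileup(consensus: str, position: int, alt: str | None = None,
                   depth: int = 10, alt_count: int = 0,
                   qual: int = 30) -> ReadPileup:
    """Reads with unique start positions 0..depth-1 running to the end of
    the consensus; the first `alt_count` carry `alt` at `position`.
    `position` must be >= depth so every read covers it."""
    assert position >= depth
    reads = []
    for i in range(depth):
        seq = consensus[i:]
        if alt is not None and i < alt_count:
            off = position - i
            seq = seq[:off] + alt + seq[off + 1:]
        reads.append(make_read(i, seq, qual=qual,
                               strand="+" if i % 2 else "-"))
    return ReadPileup(consensus=consensus, reads=reads)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
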