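from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from mirloci import (
    AlignedRead,
    FoldWindow,
    Hairpin,
    Product,
    parse_structure,
)


def make_read(start, end, strand="+", count=1, hits=1, chrom="chr1",
              name="", library="lib0"):
    return AlignedRead(chrom, start, end, strand, count=count,
                       genome_hits=hits, name=name or f"r{start}_{end}_{strand}",
                       library=library)


def make_product(spans_counts, strand="+", chrom="chr1"):
    """Product from [(start, end, count), ...]."""
    p = Product(strand=strand)
    for i, (s, e, c) in enumerate(spans_counts):
        p.reads.append(make_read(s, e, strand, count=c, chrom=chrom,
                                 name=f"pr{i}_{s}_{e}"))
    return p


@pytest.fixture
def perfect_hairpin():
    """65-nt window: arms [0,25) and [40,65), loop [25,40); perfect stem.

    Pairs are (i, 64 - i) for i < 25.  Returned as (hairpin, window,
    pair_table).
    """
    structure = "(" * 25 + "." * 15 + ")" * 25
    seq = "G" * 25 + "A" * 15 + "C" * 25
    db = parse_structure(seq, structure)
    hp = Hairpin(fivep_arm=(0, 25), loop=(25, 40), threep_arm=(40, 65),
                 n_pairs=25, hairpin_length=65)
    window = FoldWindow("chr1", 0, 65, "+")
    return hp, window, db.pair_table
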