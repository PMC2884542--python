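"""Read-region construction and candidate-locus selection.

A read region is a maximal contiguous span of overlapping aligned reads.
Regions are seeded strand-insensitively (sense and antisense reads merge into
one region) because antisense displacement is computed within a locus; the
candidate strand is decided later from product abundance.  Reads placed at
``max_hits`` or more genomic sites do not seed regions but are attached to any
region they overlap afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import AlignedRead, AnnotationInterval

__all__ = ["ReadRegion", "merge_reads_to_regions", "filter_candidate_regions"]

DEFAULT_MAX_HITS = 5
DEFAULT_MAX_REGION_LEN = 160


@dataclass
class ReadRegion:
    chrom: str
    start: int
    end: int
    reads: list[AlignedRead] = field(default_factory=list)
    is_candidate: bool = False
    rejection_tags: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def merge_reads_to_regions(
    reads: list[AlignedRead], max_hits: int = DEFAULT_MAX_HITS
) -> list[ReadRegion]:
    """Partition reads into maximal overlap-connected regions.

    Only reads with ``genome_hits < max_hits`` seed regions; once region spans
    are fixed, every read (including multi-hit ones) overlapping a region is
    attached to it.  Overlap means >= 1 shared base: bookended reads do not
    merge.
    """
    seeders = [r for r in reads if r.genome_hits < max_hits]
    regions: list[ReadRegion] = []
    by_chrom: dict[str, list[AlignedRead]] = {}
    for r in seeders:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end = rs[0].start, rs[0].end
        for r in rs[1:]:
            if r.start < cur_end:  # strict: touching spans stay separate
                cur_end = max(cur_end, r.end)
            else:
                regions.append(ReadRegion(chrom, cur_start, cur_end))
                cur_start, cur_end = r.start, r.end
        regions.append(ReadRegion(chrom, cur_start, cur_end))
    # attach all reads overlapping a fixed region
    regions.sort(key=lambda g: (g.chrom, g.start))
    idx: dict[str, list[ReadRegion]] = {}
    for g in regions:
        idx.setdefault(g.chrom, []).append(g)
    for r in sorted(reads, key=lambda r: (r.chrom, r.start, r.end, r.strand, -r.count)):
        for g in idx.get(r.chrom, ()):
            if g.overlaps(r.start, r.end):
                g.reads.append(r)
    return regions


def filter_candidate_regions(
    regions: list[ReadRegion],
    annotations: list[AnnotationInterval] = (),
    max_len: int = DEFAULT_MAX_REGION_LEN,
) -> list[ReadRegion]:
    """Mark candidate loci: length strictly < ``max_len`` and no overlap with
    any repeat/tRNA interval.  No region is deleted — non-candidates are still
    needed for neighborhood counting."""
    ann_by_chrom: dict[str, list[AnnotationInterval]] = {}
    for a in annotations:
        ann_by_chrom.setdefault(a.chrom, []).append(a)
    for g in regions:
        tags = []
        if g.length >= max_len:
            tags.append("too_long")
        for a in ann_by_chrom.get(g.chrom, ()):
            if g.overlaps(a.start, a.end):
                tag = "trna_overlap" if a.kind.lower() == "trna" else "repeat_overlap"
                if tag not in tags:
                    tags.append(tag)
        g.rejection_tags = tags
        g.is_candidate = not tags
    return regions
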