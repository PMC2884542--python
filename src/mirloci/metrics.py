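"""Per-locus quantities of the decision rule and threshold evaluation.

The predictor is a system of binary decisions: every metric is compared
against a user-configurable threshold and a locus is positive only if every
comparison passes.  All failed filters are reported, not just the first, and
the evaluation order is fixed (the order of ``evaluate_locus``'s checks).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

from .fold import FoldWindow
from .products import Product, predominant_variant

__all__ = [
    "LocusMetrics",
    "ThresholdSet",
    "compute_aapd",
    "five_prime_heterogeneity",
    "bp_per_nt",
    "same_arm_offset",
    "opposite_arm_offset",
    "abundance_metrics",
    "avg_genome_hits",
    "evaluate_locus",
]

#: returned by opposite_arm_offset when the arm products share no pairing
OPPOSITE_ARM_SENTINEL = 10_000


@dataclass
class LocusMetrics:
    """Every per-locus quantity the decision rule consumes."""

    hairpin_length: int | None = None
    total_locus_reads: int = 0
    locus_ppm: float = 0.0
    max_product_reads: int = 0
    max_product_distinct: int = 0
    aapd: float = 0.0
    five_prime_het: float | None = None
    min_bp_per_nt: float | None = None
    mir_mor_distance: int | None = None
    same_arm_offset: int = 0
    opposite_arm_offset: int | None = None
    avg_genome_hits: float | None = None
    non_mir_neighbor_count: int | None = None  # filled in pass 2


@dataclass
class ThresholdSet:
    """Named thresholds of the binary decision rule.

    ``min_*`` thresholds pass when the metric is >= the value (the top miR
    product count is strict: it must exceed ``min_top_product_reads``);
    ``max_*`` thresholds pass when the metric is <= the value.
    """

    min_hairpin_length: int = 20
    min_locus_reads: int = 5
    min_locus_ppm: float = 1.0
    min_top_product_reads: int = 1  # top miR product must have > this many reads
    min_five_prime_het: float = 0.33
    min_bp_per_nt: float = 0.55
    max_same_arm_offset: int = 3
    max_opposite_arm_offset: int = 5
    max_mir_mor_gap: int = 5
    max_aapd: float = 0.0
    max_avg_genome_hits: float = 2.0
    max_non_mir_neighbors: int = 10

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown threshold(s): {sorted(unknown)}")
        return cls(**d)


def compute_aapd(
    sense_products: list[Product],
    antisense_products: list[Product],
    sense_strand: str = "+",
) -> float:
    """Average antisense product displacement.

    For every (sense, antisense) product pair whose predominant variants
    overlap by >= 1 nt, the displacement is the absolute offset of the two
    products in genomic coordinates (sense 5' end against the antisense 3'
    end, which coincide for a perfectly matched duplex); the AAPD is the mean
    over all such pairs.  No overlapping pair -> 0 (absence of antisense
    evidence never penalizes a locus).
    """
    disps = []
    for s in sense_products:
        ss, se = s.span
        for a in antisense_products:
            as_, ae = a.span
            if ss < ae and as_ < se:
                d = abs(ss - as_) if sense_strand == "+" else abs(se - ae)
                disps.append(d)
    return sum(disps) / len(disps) if disps else 0.0


def five_prime_heterogeneity(product: Product) -> float:
    """Fraction of reads sharing the predominant variant's 5' position."""
    pv = predominant_variant(product)
    anchor = pv[0] if product.strand == "+" else pv[1]
    total = 0
    same = 0
    for s, e, c in product.variants:
        total += c
        if (s if product.strand == "+" else e) == anchor:
            same += c
    return same / total


def bp_per_nt(
    product: Product, pair_table: list[int | None], window: FoldWindow
) -> float:
    """Paired positions in the predominant span divided by span length."""
    ws, we = window.to_window(*product.span)
    n = we - ws
    if n <= 0 or we <= 0 or ws >= len(pair_table):
        return 0.0
    paired = sum(
        1 for x in range(max(0, ws), min(len(pair_table), we))
        if pair_table[x] is not None
    )
    return paired / n


def same_arm_offset(products: list[Product]) -> int:
    """Worst 5'-offset among same-arm products overlapping >= 2 nt."""
    worst = 0
    for i, p in enumerate(products):
        for q in products[i + 1:]:
            if p.overlaps(q) >= 2:
                worst = max(worst, abs(p.five_prime - q.five_prime))
    return worst


def opposite_arm_offset(
    fivep_mir: Product,
    threep_mir: Product,
    pair_table: list[int | None],
    window: FoldWindow,
) -> int:
    """Offset between the arm products after projection through the stem.

    The 3p product is projected onto the 5p arm through the pair table; the
    offset is the distance between the projection's 5'-most position and the
    5p product's 5' end.  A canonical Dicer duplex with 2-nt 3' overhangs
    projects 2 nt inside the 5p miR.  When the projection misses the 5p
    product entirely the sentinel value is returned (fails any threshold).
    """
    fs, fe = window.to_window(*fivep_mir.span)
    ts, te = window.to_window(*threep_mir.span)
    proj = [
        pair_table[x]
        for x in range(max(0, ts), min(len(pair_table), te))
        if pair_table[x] is not None
    ]
    proj = [p for p in proj if p < ts]  # partners on the 5' side of the stem
    if not proj or min(proj) >= fe or max(proj) < fs:
        return OPPOSITE_ARM_SENTINEL
    return abs(min(proj) - fs)


def abundance_metrics(
    sense_products: list[Product], total_library_reads: int
) -> tuple[int, float, int, int]:
    """(total_locus_reads, locus_ppm, max_product_reads, max_product_distinct).

    Totals are over sense-strand products only; the max is over miR-labeled
    products (0 when the locus has no miR product).
    """
    if total_library_reads <= 0:
        raise ValueError("total_library_reads must be positive")
    total = sum(p.total_count for p in sense_products)
    ppm = 1e6 * total / total_library_reads
    mirs = [p for p in sense_products if p.label in ("5p-miR", "3p-miR")]
    if mirs:
        top = max(mirs, key=lambda p: p.total_count)
        return total, ppm, top.total_count, top.n_distinct
    return total, ppm, 0, 0


def avg_genome_hits(product: Product) -> float:
    """Count-weighted mean of genome_hits over the product's reads."""
    num = sum(r.count * r.genome_hits for r in product.reads)
    den = sum(r.count for r in product.reads)
    return num / den


def evaluate_locus(
    metrics: LocusMetrics, thresholds: ThresholdSet | None = None
) -> tuple[str, list[str]]:
    """Apply every threshold; returns ('positive', []) or ('rejected', reasons).

    Metrics that are None because the corresponding product is absent
    (mir_mor_distance, opposite_arm_offset without a miR*) pass vacuously;
    non_mir_neighbor_count is skipped when unset (pass 1).
    """
    t = thresholds or ThresholdSet()
    m = metrics
    reasons: list[str] = []
    if m.hairpin_length is None:
        reasons.append("no_hairpin")
    elif m.hairpin_length < t.min_hairpin_length:
        reasons.append("hairpin_too_short")
    if m.total_locus_reads < t.min_locus_reads:
        reasons.append("few_reads")
    if m.locus_ppm < t.min_locus_ppm:
        reasons.append("low_ppm")
    if m.max_product_reads == 0:
        reasons.append("no_mir_product")
    elif m.max_product_reads <= t.min_top_product_reads:
        reasons.append("top_product_single_read")
    if m.five_prime_het is not None and m.five_prime_het < t.min_five_prime_het:
        reasons.append("five_prime_heterogeneity")
    if m.min_bp_per_nt is not None and m.min_bp_per_nt < t.min_bp_per_nt:
        reasons.append("low_pairing")
    if m.same_arm_offset > t.max_same_arm_offset:
        reasons.append("same_arm_offset")
    if (
        m.opposite_arm_offset is not None
        and m.opposite_arm_offset > t.max_opposite_arm_offset
    ):
        reasons.append("opposite_arm_offset")
    if m.mir_mor_distance is not None and m.mir_mor_distance > t.max_mir_mor_gap:
        reasons.append("mir_mor_gap")
    if m.aapd > t.max_aapd:
        reasons.append("antisense_displacement")
    if m.avg_genome_hits is not None and m.avg_genome_hits > t.max_avg_genome_hits:
        reasons.append("repeat_like")
    if (
        m.non_mir_neighbor_count is not None
        and m.non_mir_neighbor_count > t.max_non_mir_neighbors
    ):
        reasons.append("neighbor_count")
    return ("positive", []) if not reasons else ("rejected", reasons)
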