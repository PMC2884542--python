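"""Grouping of reads into products and classification on the hairpin.

A product is a group of reads whose 5' ends cluster within a small radius
(isomiR wobble from imprecise processing); its span is the span of the
predominant variant.  Products on the locus sense strand are labeled by their
position on the hairpin: miR on each arm, moR immediately distal to a miR,
loop, split (straddling a boundary with no majority), or out.  Antisense
products are grouped identically but receive no biogenesis labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import AlignedRead
from .fold import FoldWindow, Hairpin

__all__ = [
    "Product",
    "ClassifyParams",
    "group_reads_to_products",
    "classify_products",
    "predominant_variant",
]

DEFAULT_GROUP_RADIUS = 3
DEFAULT_MOR_GAP = 5


@dataclass
class ClassifyParams:
    """Structural parameters of product classification (not thresholds)."""

    group_radius: int = DEFAULT_GROUP_RADIUS
    mor_gap: int = DEFAULT_MOR_GAP


@dataclass
class Product:
    strand: str  # genomic strand of the member reads
    reads: list[AlignedRead] = field(default_factory=list)
    label: str | None = None  # 5p-miR | 3p-miR | 5p-moR | 3p-moR | loop | split | out
    arm: str = "none"  # 5p | 3p | loop | none

    @property
    def variants(self) -> list[tuple[int, int, int]]:
        """(start, end, count) per distinct span, ascending by span."""
        agg: dict[tuple[int, int], int] = {}
        for r in self.reads:
            agg[(r.start, r.end)] = agg.get((r.start, r.end), 0) + r.count
        return sorted((s, e, c) for (s, e), c in agg.items())

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.reads)

    @property
    def n_distinct(self) -> int:
        return len({(r.start, r.end) for r in self.reads})

    @property
    def span(self) -> tuple[int, int]:
        s, e, _ = predominant_variant(self)
        return s, e

    @property
    def five_prime(self) -> int:
        s, e = self.span
        return s if self.strand == "+" else e - 1

    def count_by_library(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.reads:
            out[r.library] = out.get(r.library, 0) + r.count
        return out

    def overlaps(self, other: "Product") -> int:
        s1, e1 = self.span
        s2, e2 = other.span
        return max(0, min(e1, e2) - max(s1, s2))


def predominant_variant(product: Product) -> tuple[int, int, int]:
    """Maximal-count variant; ties resolved to leftmost start, then shortest."""
    variants = product.variants
    if not variants:
        raise ValueError("empty product")
    return max(variants, key=lambda v: (v[2], -v[0], -(v[1] - v[0])))


def group_reads_to_products(
    reads: list[AlignedRead],
    strand: str,
    group_radius: int = DEFAULT_GROUP_RADIUS,
) -> list[Product]:
    """Greedy 5'-end clustering of same-strand reads, by descending count.

    Each read joins the existing product whose predominant variant's 5'
    position is within ``group_radius`` and which it overlaps by >= 1 nt
    (closest 5' wins); otherwise it founds a new product.  The result is
    independent of input order and products are sorted by genomic start.
    """
    pool = sorted(
        (r for r in reads if r.strand == strand),
        key=lambda r: (-r.count, r.start, r.end, r.library),
    )
    products: list[Product] = []
    for r in pool:
        best = None
        best_key = None
        for p in products:
            s, e = p.span
            if not (r.start < e and s < r.end):
                continue
            d = abs(r.five_prime - p.five_prime)
            if d <= group_radius:
                key = (d, s)
                if best is None or key < best_key:
                    best, best_key = p, key
        if best is None:
            products.append(Product(strand=strand, reads=[r]))
        else:
            best.reads.append(r)
    products.sort(key=lambda p: p.span)
    return products


def _zone_bases(ws: int, we: int, zone: tuple[int, int]) -> int:
    return max(0, min(we, zone[1]) - max(ws, zone[0]))


def _paired_fraction(pt, ws: int, we: int) -> float:
    n = we - ws
    if n <= 0:
        return 0.0
    paired = sum(
        1 for x in range(max(0, ws), min(len(pt), we)) if pt[x] is not None
    )
    return paired / n


def classify_products(
    products: list[Product],
    hairpin: Hairpin,
    window: FoldWindow,
    pair_table: list[int | None],
    params: ClassifyParams | None = None,
) -> list[Product]:
    """Assign hairpin-position labels to sense-strand products.

    Zone (5p arm / loop / 3p arm / outside) is assigned by strict base
    majority of the predominant span; an exact straddle is ``split``.  On each
    arm the highest-count product lying mostly on paired stem is the miR; a
    product immediately distal to the miR (gap <= ``mor_gap``) is the moR.
    Excess products on an arm are labeled ``out``.
    """
    params = params or ClassifyParams()
    if hairpin is None:
        for p in products:
            p.label, p.arm = "out", "none"
        return products

    zones = {"5p": hairpin.fivep_arm, "loop": hairpin.loop, "3p": hairpin.threep_arm}
    wspans = {}
    for p in products:
        ws, we = window.to_window(*p.span)
        wspans[id(p)] = (ws, we)
        n = we - ws
        counts = {z: _zone_bases(ws, we, span) for z, span in zones.items()}
        counts["outside"] = n - sum(counts.values())
        best_zone = max(counts, key=lambda z: (counts[z], z))
        if counts[best_zone] * 2 > n:
            zone = best_zone
        else:
            zone = "split"
        if zone == "outside":
            p.label, p.arm = "out", "none"
        elif zone == "loop":
            p.label, p.arm = "loop", "loop"
        elif zone == "split":
            p.label, p.arm = "split", "none"
        else:
            p.label, p.arm = None, zone  # arm product, role decided below

    for arm in ("5p", "3p"):
        arm_products = [p for p in products if p.arm == arm and p.label is None]
        mir = None
        candidates = [
            p
            for p in arm_products
            if _paired_fraction(pair_table, *wspans[id(p)]) > 0.5
        ]
        if candidates:
            mir = max(
                candidates, key=lambda p: (p.total_count, -wspans[id(p)][0])
            )
            mir.label = f"{arm}-miR"
        # moR: immediately distal (toward the hairpin's outside) to the miR
        if mir is not None:
            mws, mwe = wspans[id(mir)]
            mor_candidates = []
            for p in products:
                if p is mir or p.label not in (None, "out"):
                    continue
                ws, we = wspans[id(p)]
                gap = mws - we if arm == "5p" else ws - mwe
                if 0 <= gap <= params.mor_gap:
                    mor_candidates.append((p, gap))
            if mor_candidates:
                mor = max(mor_candidates, key=lambda t: (t[0].total_count, -t[1]))[0]
                mor.label = f"{arm}-moR"
        for p in arm_products:
            if p.label is None:
                p.label = "out"
    return products
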