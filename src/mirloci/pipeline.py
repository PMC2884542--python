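"""End-to-end two-pass prediction and neighborhood filtering.

Pass 1 takes each candidate read region through folding, product grouping and
classification, computes the locus metrics and applies the biogenesis
thresholds.  Pass 2 computes, for every provisional positive, the number of
read regions within +/- 1 kb that do not overlap any pass-1 positive locus
(the non-miR neighborhood density of degradation-rich regions) and rejects
loci exceeding the neighbor threshold.  Pass 2 runs once; the exclusion set
is the pass-1 provisional positive set, so tandem miR clusters never reject
each other.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

from .io import AlignedRead, AnnotationInterval, GenomeSequence, PredictionRecord
from .regions import ReadRegion, merge_reads_to_regions, filter_candidate_regions
from .fold import FoldWindow, select_fold_windows, fold_sequence, extract_hairpins
from .products import ClassifyParams, group_reads_to_products, classify_products
from . import metrics as M

__all__ = [
    "PipelineConfig",
    "non_mir_neighbor_count",
    "analyze_loci",
    "two_pass_predict",
    "apply_two_pass",
    "assign_family",
    "load_reference_matures",
]

DEFAULT_NEIGHBOR_HALF_WINDOW = 1000


@dataclass
class PipelineConfig:
    """Structural parameters of the pipeline (distinct from the thresholds)."""

    window_size: int = 150
    max_seed_hits: int = 5
    max_region_length: int = 160
    group_radius: int = 3
    mor_gap: int = 5
    merge_gap: int = 8
    neighbor_half_window: int = DEFAULT_NEIGHBOR_HALF_WINDOW
    engine: str = "auto"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline parameter(s): {sorted(unknown)}")
        return cls(**d)


def non_mir_neighbor_count(
    locus: tuple[str, int, int],
    all_read_regions: list[ReadRegion],
    positive_loci: list[tuple[str, int, int]],
    half_window: int = DEFAULT_NEIGHBOR_HALF_WINDOW,
    own_region: ReadRegion | None = None,
) -> int:
    """Read regions near a locus that do not overlap any positive locus.

    Counts regions intersecting ``[start - half_window, end + half_window)``
    on the locus chromosome, excluding the locus's own region and any region
    overlapping a predicted positive locus.  All regions participate,
    including repeat/tRNA-overlapping and over-length ones.
    """
    chrom, start, end = locus
    lo, hi = start - half_window, end + half_window
    pos = [(s, e) for c, s, e in positive_loci if c == chrom]
    n = 0
    for g in all_read_regions:
        if g is own_region or g.chrom != chrom:
            continue
        if not (g.start < hi and lo < g.end):
            continue
        if any(g.start < e and s < g.end for s, e in pos):
            continue
        n += 1
    return n


def _choose_hairpin(region, genome, strand, cfg, min_hairpin_length):
    """Fold up to three windows; keep the hairpin with the most read-covered
    paired bases (ties: more stem pairs, then leftmost window, then leftmost
    hairpin)."""
    sense_reads = [r for r in region.reads if r.strand == strand]
    best = None
    best_key = None
    for ws, we in select_fold_windows(region, genome, cfg.window_size):
        window = FoldWindow(region.chrom, ws, we, strand)
        db = fold_sequence(window.sequence(genome), cfg.engine)
        covered = [False] * (we - ws)
        for r in sense_reads:
            a, b = window.to_window(r.start, r.end)
            for x in range(max(0, a), min(we - ws, b)):
                covered[x] = True
        for hp in extract_hairpins(db, min_hairpin_length, cfg.merge_gap):
            s, e = hp.span
            score = sum(
                1
                for x in range(s, e)
                if covered[x] and db.pair_table[x] is not None
            )
            key = (score, hp.n_pairs, -window.start, -s)
            if best is None or key > best_key:
                best = (window, db, hp)
                best_key = key
    return best  # None when no window folds into any hairpin


def _analyze_candidate(
    region: ReadRegion,
    genome: dict[str, GenomeSequence],
    cfg: PipelineConfig,
    min_hairpin_length: int,
    total_library_reads: int,
    chrom_reads: list[AlignedRead] | None = None,
) -> PredictionRecord:
    by_strand = {"+": 0, "-": 0}
    for r in region.reads:
        by_strand[r.strand] += r.count
    strand = "+" if by_strand["+"] >= by_strand["-"] else "-"
    anti = "-" if strand == "+" else "+"

    params = ClassifyParams(group_radius=cfg.group_radius, mor_gap=cfg.mor_gap)
    m = M.LocusMetrics()
    chosen = _choose_hairpin(region, genome, strand, cfg, min_hairpin_length)
    mature_seq = ""
    # The locus is the folded hairpin; once folded, all reads overlapping it
    # (which may span several read regions: miR, miR* and moRs need not
    # overlap each other genomically) are grouped into products.
    if chosen is not None:
        window, db, hp = chosen
        locus_start, locus_end = window.to_genomic(*hp.span)
    else:
        locus_start, locus_end = region.start, region.end
    pool = chrom_reads if chrom_reads is not None else region.reads
    locus_reads = [
        r for r in pool
        if r.chrom == region.chrom and r.overlaps(locus_start, locus_end)
    ]
    sense_products = group_reads_to_products(locus_reads, strand, cfg.group_radius)
    antisense_products = group_reads_to_products(locus_reads, anti, cfg.group_radius)
    if chosen is not None:
        classify_products(sense_products, hp, window, db.pair_table, params)
        m.hairpin_length = hp.hairpin_length
        mirs = {p.label: p for p in sense_products if p.label in ("5p-miR", "3p-miR")}
        mors = {p.label: p for p in sense_products if p.label in ("5p-moR", "3p-moR")}
        if mirs:
            top = max(mirs.values(), key=lambda p: p.total_count)
            m.five_prime_het = M.five_prime_heterogeneity(top)
            m.avg_genome_hits = M.avg_genome_hits(top)
            m.min_bp_per_nt = min(
                M.bp_per_nt(p, db.pair_table, window) for p in mirs.values()
            )
            mature_seq = genome[region.chrom].fetch(*top.span, strand)
        gaps = []
        for arm in ("5p", "3p"):
            mir, mor = mirs.get(f"{arm}-miR"), mors.get(f"{arm}-moR")
            if mir and mor:
                (ms, me) = window.to_window(*mir.span)
                (os_, oe) = window.to_window(*mor.span)
                gaps.append(ms - oe if arm == "5p" else os_ - me)
        m.mir_mor_distance = max(gaps) if gaps else None
        m.same_arm_offset = max(
            (
                M.same_arm_offset([p for p in sense_products if p.arm == arm])
                for arm in ("5p", "3p")
            ),
            default=0,
        )
        if "5p-miR" in mirs and "3p-miR" in mirs:
            m.opposite_arm_offset = M.opposite_arm_offset(
                mirs["5p-miR"], mirs["3p-miR"], db.pair_table, window
            )
    else:
        for p in sense_products:
            p.label, p.arm = "out", "none"

    (
        m.total_locus_reads,
        m.locus_ppm,
        m.max_product_reads,
        m.max_product_distinct,
    ) = M.abundance_metrics(sense_products, total_library_reads)
    m.aapd = M.compute_aapd(sense_products, antisense_products, strand)

    rec = PredictionRecord(
        chrom=region.chrom,
        start=locus_start,
        end=locus_end,
        strand=strand,
        verdict="rejected",
        reasons=["unevaluated"],
        products=sense_products,
        antisense_products=antisense_products,
        metrics=m,
        mature_seq=mature_seq,
    )
    rec.region = region
    return rec


def apply_two_pass(
    records: list[PredictionRecord],
    all_regions: list[ReadRegion],
    thresholds: M.ThresholdSet | None = None,
    half_window: int = DEFAULT_NEIGHBOR_HALF_WINDOW,
) -> list[PredictionRecord]:
    """Evaluate thresholds (pass 1) then neighborhood filtering (pass 2).

    Operates on already-computed metrics, so the same records can be
    re-evaluated under different threshold sets without re-folding.
    """
    t = thresholds or M.ThresholdSet()
    for rec in records:
        rec.metrics.non_mir_neighbor_count = None
        verdict, reasons = M.evaluate_locus(rec.metrics, t)
        rec.verdict, rec.reasons = verdict, reasons
    provisional = [r for r in records if r.verdict == "positive"]
    pos_spans = [(r.chrom, r.start, r.end) for r in provisional]
    for rec in provisional:
        nmc = non_mir_neighbor_count(
            (rec.chrom, rec.start, rec.end),
            all_regions,
            pos_spans,
            half_window,
            own_region=getattr(rec, "region", None),
        )
        rec.metrics.non_mir_neighbor_count = nmc
        if nmc > t.max_non_mir_neighbors:
            rec.verdict = "rejected"
            rec.reasons = ["neighbor_count"]
    return records


def analyze_loci(
    reads: list[AlignedRead],
    genome: dict[str, GenomeSequence],
    annotations: list[AnnotationInterval] = (),
    thresholds: M.ThresholdSet | None = None,
    config: PipelineConfig | None = None,
    total_library_reads: int | None = None,
) -> tuple[list[PredictionRecord], list[ReadRegion]]:
    """Pass-1 analysis without threshold evaluation.

    Returns unevaluated per-locus records plus every read region (needed for
    neighborhood counting); feed both to :func:`apply_two_pass`, possibly
    repeatedly under different threshold sets.
    """
    cfg = config or PipelineConfig()
    t = thresholds or M.ThresholdSet()
    if not reads:
        return [], []
    regions = merge_reads_to_regions(reads, cfg.max_seed_hits)
    filter_candidate_regions(regions, annotations, cfg.max_region_length)
    total = total_library_reads or sum(r.count for r in reads)
    by_chrom: dict[str, list[AlignedRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    records = [
        _analyze_candidate(g, genome, cfg, t.min_hairpin_length, total,
                           by_chrom.get(g.chrom))
        for g in regions
        if g.is_candidate
    ]
    # Neighboring read regions (e.g. the miR, miR* and moR fragments of one
    # locus) can converge on the same or a near-identical hairpin; collapse
    # overlapping same-strand locus records to the best-supported one
    # (most locus reads, then longer hairpin, then leftmost).
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    unique: list[PredictionRecord] = []
    for rec in records:
        prev = unique[-1] if unique else None
        if (
            prev is not None
            and prev.chrom == rec.chrom
            and prev.strand == rec.strand
            and rec.start < prev.end
            and prev.start < rec.end
        ):
            def _rank(r):
                return (
                    r.metrics.total_locus_reads,
                    r.metrics.hairpin_length or 0,
                    -r.start,
                )
            if _rank(rec) > _rank(prev):
                unique[-1] = rec
            continue
        unique.append(rec)
    return unique, regions


def two_pass_predict(
    reads: list[AlignedRead],
    genome: dict[str, GenomeSequence],
    annotations: list[AnnotationInterval] = (),
    thresholds: M.ThresholdSet | None = None,
    config: PipelineConfig | None = None,
    total_library_reads: int | None = None,
) -> list[PredictionRecord]:
    """Full two-pass prediction; deterministic given identical inputs."""
    cfg = config or PipelineConfig()
    t = thresholds or M.ThresholdSet()
    records, regions = analyze_loci(
        reads, genome, annotations, t, cfg, total_library_reads
    )
    apply_two_pass(records, regions, t, cfg.neighbor_half_window)
    return records


def _hamming_over_shorter(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def assign_family(
    mature_seq: str,
    reference_matures: list[tuple[str, str, str]],
    max_mismatches: int = 4,
) -> str | None:
    """Family of a mature sequence by seed identity plus mature similarity.

    Requires an exact seed match (nucleotides 2-7, 1-based, of the mature)
    and at most ``max_mismatches`` mismatches against a known member's mature
    sequence, compared 5'-anchored and ungapped over the shorter length
    (length difference is not counted).  Ties go to the smallest distance,
    then the lexicographically first family.
    """
    q = mature_seq.upper().replace("U", "T")
    if len(q) < 7:
        return None
    seed = q[1:7]
    hits = []
    for name, family, mature in reference_matures:
        r = mature.upper().replace("U", "T")
        if len(r) < 7 or r[1:7] != seed:
            continue
        d = _hamming_over_shorter(q, r)
        if d <= max_mismatches:
            hits.append((d, family, name))
    if not hits:
        return None
    return min(hits)[1]


def load_reference_matures(path) -> list[tuple[str, str, str]]:
    """Reference mature-miR FASTA -> (name, family, mature) records.

    The family is taken from a ``family=<x>`` token in the description when
    present, otherwise the record name itself is used.
    """
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        family = rec.id
        for token in rec.description.split():
            if token.startswith("family="):
                family = token[len("family="):]
        out.append((rec.id, family, str(rec.seq).upper().replace("U", "T")))
    return out
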