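"""Input/output and core genomic data types.

All internal coordinates are 0-based, half-open.  BED is native; GFF3 is
converted to 1-based inclusive at the boundary.  Genomes are stored as
uppercase DNA (U is converted to T on load).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "AlignedRead",
    "AnnotationInterval",
    "PredictionRecord",
    "load_genome",
    "load_alignments",
    "load_annotations",
    "write_alignments_bed",
    "write_predictions",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One reference sequence (chromosome/scaffold)."""

    name: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Subsequence on the requested strand, 0-based half-open."""
        sub = self.seq[max(0, start):end]
        return revcomp(sub) if strand == "-" else sub


@dataclass
class AlignedRead:
    """One genomic placement of a (collapsed) sequenced small RNA.

    ``count`` is the number of identical reads collapsed into this record and
    ``genome_hits`` the number of placements of the read genome-wide.
    """

    chrom: str
    start: int
    end: int
    strand: str
    seq: str = ""
    count: int = 1
    genome_hits: int = 1
    name: str = ""
    library: str = "lib0"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty read span {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.count < 1 or self.genome_hits < 1:
            raise ValueError("count and genome_hits must be >= 1")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (0-based base position)."""
        return self.start if self.strand == "+" else self.end - 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class AnnotationInterval:
    chrom: str
    start: int
    end: int
    kind: str = "other"  # repeat | tRNA | other

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("annotation interval must satisfy start < end")


@dataclass
class PredictionRecord:
    """Verdict, metrics and labeled products for one candidate locus."""

    chrom: str
    start: int
    end: int
    strand: str
    verdict: str  # positive | rejected
    reasons: list[str] = field(default_factory=list)
    products: list = field(default_factory=list)  # classified sense Products
    antisense_products: list = field(default_factory=list)
    metrics: object | None = None
    mature_seq: str = ""
    family: str | None = None

    def __post_init__(self) -> None:
        if self.verdict == "positive" and self.reasons:
            raise ValueError("positive record cannot carry rejection reasons")


class FastaParseError(ValueError):
    pass


def load_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Load a FASTA genome; sequences uppercased, U converted to T.

    Raises on duplicate identifiers and on files that do not start with a
    FASTA header line.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise FastaParseError(
                f"{path}: not FASTA, first line {first.strip()!r}"
            )
    genome: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FastaParseError(f"{path}: duplicate sequence identifier {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        genome[rec.id] = GenomeSequence(rec.id, seq)
    return genome


_NAME_COUNT_RE = re.compile(r"[_-]x?(\d+)$")


def _read_count_from_name(name: str) -> int | None:
    m = _NAME_COUNT_RE.search(name)
    return int(m.group(1)) if m else None


def _collapse(reads: list[AlignedRead]) -> list[AlignedRead]:
    """Merge identical placements (chrom, span, strand, library): counts sum."""
    merged: dict[tuple, AlignedRead] = {}
    for r in reads:
        key = (r.chrom, r.start, r.end, r.strand, r.library)
        if key in merged:
            merged[key].count += r.count
        else:
            merged[key] = r
    return sorted(
        merged.values(), key=lambda r: (r.chrom, r.start, r.end, r.strand)
    )


def load_alignments(
    path: str | Path,
    *,
    genome: Mapping[str, GenomeSequence] | None = None,
    hits_table: Mapping[str, int] | None = None,
    library: str | None = None,
    min_len: int = 15,
    max_len: int = 35,
) -> tuple[list[AlignedRead], int]:
    """Load strand-aware read alignments from BED6 or SAM/BAM.

    Read count channel: BED score column; SAM integer tag ``XC`` or a
    collapsed-name suffix (``name_x12``), else 1.  genome_hits channel
    precedence: SAM ``NH`` tag > ``hits_table`` > number of placements of the
    read name within the file.

    Returns ``(reads, n_skipped)`` where ``n_skipped`` counts alignments on
    chromosomes absent from ``genome`` (when a genome is supplied) or with
    out-of-bounds lengths.
    """
    path = Path(path)
    library = library if library is not None else path.stem
    suffix = path.suffix.lower()
    if suffix in (".sam", ".bam", ".cram"):
        raw = _load_sam(path, hits_table, library)
    else:
        raw = _load_bed(path, hits_table, library)

    reads: list[AlignedRead] = []
    skipped = 0
    for r in raw:
        if genome is not None and r.chrom not in genome:
            skipped += 1
            continue
        if not (min_len <= r.end - r.start <= max_len):
            skipped += 1
            continue
        if not r.seq and genome is not None:
            r.seq = genome[r.chrom].fetch(r.start, r.end, r.strand)
        reads.append(r)
    return _collapse(reads), skipped


def _load_bed(path: Path, hits_table, library: str) -> list[AlignedRead]:
    rows = []
    placements: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: BED6 needs 6 columns, got {len(parts)}")
            chrom, start, end, name, score, strand = parts[:6]
            try:
                count = int(score)
            except ValueError:
                raise ValueError(
                    f"{path}:{ln}: read-count channel absent "
                    f"(BED score column {score!r} is not an integer)"
                ) from None
            if count < 1:
                raise ValueError(f"{path}:{ln}: read count must be >= 1, got {count}")
            rows.append((chrom, int(start), int(end), name, count, strand))
            placements[name] = placements.get(name, 0) + 1
    reads = []
    for chrom, start, end, name, count, strand in rows:
        if hits_table is not None and name in hits_table:
            hits = int(hits_table[name])
        else:
            hits = placements[name]
        reads.append(
            AlignedRead(chrom, start, end, strand, count=count,
                        genome_hits=hits, name=name, library=library)
        )
    return reads


def _load_sam(path: Path, hits_table, library: str) -> list[AlignedRead]:
    import pysam

    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    rows = []
    placements: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            name = aln.query_name or ""
            if aln.has_tag("XC"):
                count = int(aln.get_tag("XC"))
            else:
                count = _read_count_from_name(name) or 1
            nh = int(aln.get_tag("NH")) if aln.has_tag("NH") else None
            seq = (aln.query_sequence or "").upper().replace("U", "T")
            strand = "-" if aln.is_reverse else "+"
            if aln.is_reverse and seq:
                # SAM stores reference-forward sequence; keep read orientation
                seq = revcomp(seq)
            rows.append(
                (aln.reference_name, aln.reference_start, aln.reference_end,
                 strand, seq, count, nh, name)
            )
            placements[name] = placements.get(name, 0) + 1
    reads = []
    for chrom, start, end, strand, seq, count, nh, name in rows:
        if nh is not None:
            hits = nh
        elif hits_table is not None and name in hits_table:
            hits = int(hits_table[name])
        else:
            hits = placements[name]
        reads.append(
            AlignedRead(chrom, start, end, strand, seq=seq, count=count,
                        genome_hits=hits, name=name, library=library)
        )
    return reads


def load_annotations(path: str | Path, kind: str = "other") -> list[AnnotationInterval]:
    """Load repeat/tRNA intervals from BED (0-based) or GFF3 (1-based)."""
    path = Path(path)
    is_gff = path.suffix.lower() in (".gff", ".gff3", ".gtf")
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if is_gff:
                chrom, start, end = parts[0], int(parts[3]) - 1, int(parts[4])
                k = parts[2] if len(parts) > 2 else kind
            else:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                k = kind
            out.append(AnnotationInterval(chrom, start, end, k))
    return out


def write_alignments_bed(reads: Iterable[AlignedRead], path: str | Path) -> None:
    """Write reads as BED6 (score column = collapsed count)."""
    with open(path, "w") as fh:
        for r in sorted(reads, key=lambda r: (r.chrom, r.start, r.end, r.strand)):
            name = r.name or f"read_{r.chrom}_{r.start}_{r.strand}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{r.count}\t{r.strand}\n")


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


_TSV_METRIC_COLS = [
    "hairpin_length", "total_locus_reads", "locus_ppm", "max_product_reads",
    "max_product_distinct", "aapd", "five_prime_het", "min_bp_per_nt",
    "mir_mor_distance", "same_arm_offset", "opposite_arm_offset",
    "avg_genome_hits", "non_mir_neighbor_count",
]


def write_predictions(
    records: Sequence[PredictionRecord],
    out_dir: str | Path,
    *,
    libraries: Sequence[str] = (),
) -> tuple[Path, Path]:
    """Write predictions as GFF3 (positives) and a per-locus metrics TSV.

    GFF3 uses 1-based inclusive coordinates; the locus feature has one child
    feature per labeled product.  Output ordering and float formatting are
    fixed, so identical inputs yield byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gff_path = out_dir / "predictions.gff3"
    tsv_path = out_dir / "predictions.tsv"
    recs = sorted(records, key=lambda r: (r.chrom, r.start, r.end, r.strand))

    type_for = {"5p-miR": "miRNA", "3p-miR": "miRNA",
                "5p-moR": "ncRNA", "3p-moR": "ncRNA", "loop": "ncRNA"}
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        idx = 0
        for rec in recs:
            if rec.verdict != "positive":
                continue
            idx += 1
            lid = f"mirlocus_{idx:04d}"
            fh.write(
                f"{rec.chrom}\tmirloci\tmiRNA_primary_transcript\t"
                f"{rec.start + 1}\t{rec.end}\t.\t{rec.strand}\t.\t"
                f"ID={lid};reads={_fmt(getattr(rec.metrics, 'total_locus_reads', None))}\n"
            )
            for j, p in enumerate(rec.products, 1):
                if p.label in ("out", "split", None):
                    continue
                fh.write(
                    f"{rec.chrom}\tmirloci\t{type_for.get(p.label, 'ncRNA')}\t"
                    f"{p.span[0] + 1}\t{p.span[1]}\t.\t{rec.strand}\t.\t"
                    f"ID={lid}.{j};Parent={lid};label={p.label};"
                    f"reads={p.total_count}\n"
                )

    lib_cols = [f"reads_{lib}" for lib in libraries] if len(libraries) > 1 else []
    header = (
        ["chrom", "start", "end", "strand", "verdict", "reasons",
         "n_products", "product_labels", "mature_seq", "family"]
        + _TSV_METRIC_COLS + lib_cols
    )
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for rec in recs:
            labels = ",".join(
                f"{p.label}:{p.total_count}" for p in rec.products if p.label
            )
            row = [
                rec.chrom, rec.start, rec.end, rec.strand, rec.verdict,
                ",".join(rec.reasons) or ".", len(rec.products), labels or ".",
                rec.mature_seq or ".", rec.family or ".",
            ]
            for col in _TSV_METRIC_COLS:
                row.append(_fmt(getattr(rec.metrics, col, None)))
            if lib_cols:
                per_lib = {lib: 0 for lib in libraries}
                for p in rec.products:
                    for lib, c in p.count_by_library().items():
                        per_lib[lib] = per_lib.get(lib, 0) + c
                row.extend(per_lib[lib] for lib in libraries)
            fh.write("\t".join(_fmt(x) for x in row) + "\n")
    return gff_path, tsv_path
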