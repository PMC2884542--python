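"""Seeded synthetic datasets with per-locus ground truth.

The generator plants three locus classes on a random genome:

* ``mir`` — an inverted repeat folding into a perfect-stem hairpin emitting
  miR (dominant), miR* at the stem-projected position with a canonical 2-nt
  3' overhang, an optional moR immediately outside the miR, optional loop
  reads, and 5'-wobbled isomiR reads;
* ``sirna_decoy`` — the same hairpin and sense reads plus antisense reads
  whose 5' ends are shifted by several nucleotides, the signature of
  endo-siRNA/piRNA processing;
* ``degradation`` — a valid miR hairpin surrounded by > 10 scattered
  single-read regions within +/- 1 kb, emulating a degradation-rich
  neighborhood (rejected only in pass 2).

Low-abundance background reads are scattered uniformly away from planted
loci.  Each planted hairpin is flanked by a 25-nt A/C-only buffer (A and C
cannot base-pair with each other), emulating the weakly structured flanks of
pri-miRNAs and keeping the planted stem the unambiguous fold.  All randomness
derives from the single seed; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import AlignedRead, GenomeSequence, revcomp, write_alignments_bed

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "HostGene",
    "SimulatedDataset",
    "simulate_dataset",
    "generate_dataset",
    "plant_mirtron",
]

ARM_LEN = 30
LOOP_LEN = 6
BUFFER_LEN = 25
MIR_LEN = 22
MIR_OFFSET = 4  # miR 5' offset into the 5p arm
MOR_GAP = 1  # gap between 5p-moR 3' end and miR 5' end
MIN_SLOT = 2600  # genomic spacing budget per planted locus


@dataclass
class SimulationConfig:
    seed: int = 1
    genome_length: int = 100_000
    n_mir_loci: int = 20
    n_sirna_decoys: int = 10
    n_degradation_patches: int = 5
    mir_depth: int = 100
    mirstar_fraction: float = 0.02
    mor_fraction: float = 0.01
    loop_fraction: float = 0.0001
    isomir_wobble: int = 1
    isomir_fraction: float = 0.1
    antisense_offset_decoy: int = 8
    decoy_antisense_fraction: float = 0.5
    n_scatter_per_patch: int = 12
    background_rate: float = 0.2  # reads per kb, away from planted loci
    chrom_name: str = "chrSim"

    def __post_init__(self) -> None:
        for name in ("mirstar_fraction", "mor_fraction", "loop_fraction",
                     "isomir_fraction", "decoy_antisense_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mirstar_fraction >= 1.0:
            raise ValueError("mirstar_fraction must be < 1 (miR must dominate)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthRecord:
    chrom: str
    start: int
    end: int
    strand: str
    locus_class: str  # mir | sirna_decoy | degradation | background
    expected_verdict: str  # positive | rejected
    expected_rejection_reason: str = ""


@dataclass
class HostGene:
    """Minimal host-gene model for mirtron planting: one intron span."""

    chrom: str
    intron_start: int
    intron_length: int


@dataclass
class SimulatedDataset:
    genome: dict[str, GenomeSequence]
    reads: list[AlignedRead]
    truths: list[TruthRecord]
    config: SimulationConfig = field(default_factory=SimulationConfig)


_BASES = np.array(list("ACGT"))
_AC = np.array(list("AC"))


def _random_arm(rng: np.random.Generator, length: int = ARM_LEN) -> str:
    """Random arm sequence with no homopolymer run of four, so the perfect
    inverted repeat is the unambiguous fold (no register slippage)."""
    while True:
        arm = "".join(rng.choice(_BASES, size=length))
        if not any(b * 4 in arm for b in "ACGT"):
            return arm


class _ReadEmitter:
    def __init__(self, chrom: str, library: str = "simlib"):
        self.chrom = chrom
        self.library = library
        self.reads: list[AlignedRead] = []
        self._n = 0

    def emit(self, start: int, end: int, strand: str, count: int, seq: str = "") -> None:
        if count < 1:
            return
        self._n += 1
        self.reads.append(
            AlignedRead(self.chrom, start, end, strand, seq=seq, count=count,
                        genome_hits=1, name=f"sim_r{self._n:06d}",
                        library=self.library)
        )


def _plant_hairpin(genome: np.ndarray, h: int, rng: np.random.Generator) -> None:
    """Write buffer + perfect stem-loop + buffer into the genome at h."""
    arm1 = _random_arm(rng)
    loop = "".join(rng.choice(_AC, size=LOOP_LEN))
    hairpin = arm1 + loop + revcomp(arm1)
    left = "".join(rng.choice(_AC, size=BUFFER_LEN))
    right = "".join(rng.choice(_AC, size=BUFFER_LEN))
    block = left + hairpin + right
    genome[h - BUFFER_LEN:h - BUFFER_LEN + len(block)] = list(block)


def _emit_mir_reads(cfg: SimulationConfig, em: _ReadEmitter, h: int,
                    with_mor: bool = True) -> None:
    """Emit the product stoichiometry of one planted miR hairpin at h."""
    L = 2 * ARM_LEN + LOOP_LEN
    mir_s = h + MIR_OFFSET
    em.emit(mir_s, mir_s + MIR_LEN, "+", cfg.mir_depth)
    wobble = round(cfg.mir_depth * cfg.isomir_fraction)
    if cfg.isomir_wobble > 0 and wobble > 0:
        em.emit(mir_s + cfg.isomir_wobble, mir_s + MIR_LEN + cfg.isomir_wobble,
                "+", wobble)
    # miR*: stem projection of the miR with a 2-nt 3' overhang (sense strand)
    star_count = max(1, round(cfg.mir_depth * cfg.mirstar_fraction))
    if cfg.mirstar_fraction > 0:
        t_hi = L - 1 - (MIR_OFFSET + 2)          # partner of miR 5' + overhang
        t_lo = L - 1 - (MIR_OFFSET + 2 + MIR_LEN - 1)
        em.emit(h + t_lo, h + t_hi + 1, "+", star_count)
    if with_mor and cfg.mor_fraction > 0:
        mor_count = max(1, round(cfg.mir_depth * cfg.mor_fraction))
        em.emit(mir_s - MIR_LEN - MOR_GAP, mir_s - MOR_GAP, "+", mor_count)
    loop_count = round(cfg.mir_depth * cfg.loop_fraction)
    if loop_count > 0:
        em.emit(h + ARM_LEN, h + ARM_LEN + LOOP_LEN, "+", loop_count)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Build the genome, reads and truth table for one configuration."""
    rng = np.random.default_rng(cfg.seed)
    n_loci = cfg.n_mir_loci + cfg.n_sirna_decoys + cfg.n_degradation_patches
    if n_loci > 0:
        slot = cfg.genome_length // n_loci
        if slot < MIN_SLOT:
            raise ValueError(
                f"genome too short for {n_loci} loci: need at least "
                f"{n_loci * MIN_SLOT} nt, got {cfg.genome_length}"
            )
    genome = rng.choice(_BASES, size=cfg.genome_length)
    em = _ReadEmitter(cfg.chrom_name)
    truths: list[TruthRecord] = []

    classes = (
        ["mir"] * cfg.n_mir_loci
        + ["sirna_decoy"] * cfg.n_sirna_decoys
        + ["degradation"] * cfg.n_degradation_patches
    )
    classes = [classes[i] for i in rng.permutation(len(classes))]
    L = 2 * ARM_LEN + LOOP_LEN

    planted_spans: list[tuple[int, int]] = []
    for i, cls in enumerate(classes):
        slot = cfg.genome_length // n_loci
        h = slot * i + slot // 2
        _plant_hairpin(genome, h, rng)
        planted_spans.append((h - BUFFER_LEN, h + L + BUFFER_LEN))
        _emit_mir_reads(cfg, em, h)
        if cls == "mir":
            truths.append(TruthRecord(cfg.chrom_name, h, h + L, "+", "mir",
                                      "positive"))
        elif cls == "sirna_decoy":
            off = cfg.antisense_offset_decoy
            anti_count = max(1, round(cfg.mir_depth * cfg.decoy_antisense_fraction))
            mir_s = h + MIR_OFFSET
            em.emit(mir_s + off, mir_s + MIR_LEN + off, "-", anti_count)
            if off > 0:
                truths.append(TruthRecord(cfg.chrom_name, h, h + L, "+",
                                          "sirna_decoy", "rejected",
                                          "antisense_displacement"))
            else:  # coincident antisense products are miR-compatible
                truths.append(TruthRecord(cfg.chrom_name, h, h + L, "+",
                                          "sirna_decoy", "positive"))
        else:  # degradation patch: hairpin valid, neighborhood is not
            n_left = cfg.n_scatter_per_patch // 2
            n_right = cfg.n_scatter_per_patch - n_left
            offsets = np.concatenate([
                np.linspace(-950, -330, n_left),
                np.linspace(L + 330, L + 950, n_right),
            ])
            for off in offsets:
                p = h + int(off) + int(rng.integers(-20, 21))
                em.emit(p, p + 21, "+", 1)
                truths.append(TruthRecord(cfg.chrom_name, p, p + 21, "+",
                                          "background", "rejected", "few_reads"))
            truths.append(TruthRecord(cfg.chrom_name, h, h + L, "+",
                                      "degradation", "rejected", "neighbor_count"))

    n_bg = round(cfg.background_rate * cfg.genome_length / 1000)
    placed = 0
    attempts = 0
    while placed < n_bg and attempts < 10_000:
        attempts += 1
        p = int(rng.integers(0, max(1, cfg.genome_length - 25)))
        if any(s - 1200 < p < e + 1200 for s, e in planted_spans):
            continue
        em.emit(p, p + 20, "+", 1)
        truths.append(TruthRecord(cfg.chrom_name, p, p + 20, "+", "background",
                                  "rejected", "few_reads"))
        placed += 1

    gseq = "".join(genome)
    gdict = {cfg.chrom_name: GenomeSequence(cfg.chrom_name, gseq)}
    for r in em.reads:
        r.seq = gdict[cfg.chrom_name].fetch(r.start, r.end, r.strand)
    return SimulatedDataset(gdict, em.reads, truths, cfg)


def plant_mirtron(cfg: SimulationConfig, host: HostGene,
                  genome: np.ndarray, emitter: _ReadEmitter,
                  rng: np.random.Generator) -> TruthRecord:
    """Plant a hairpin that coincides exactly with a short intron.

    The hairpin ends abut the splice sites; reads are emitted as an ordinary
    miR locus without moRs (mirtrons bypass the Drosha step that produces
    them).  Raises when the intron cannot host a valid miR duplex.
    """
    Lint = host.intron_length
    arm = (Lint - 4) // 2
    loop = Lint - 2 * arm
    if arm < MIR_LEN + 2 or not 3 <= loop <= 15:
        raise ValueError(
            f"intron of {Lint} nt cannot host a miR hairpin "
            f"(need >= {2 * (MIR_LEN + 2) + 4} nt)"
        )
    h = host.intron_start
    arm1 = _random_arm(rng, arm)
    loop_seq = "".join(rng.choice(_AC, size=loop))
    block = ("".join(rng.choice(_AC, size=BUFFER_LEN))
             + arm1 + loop_seq + revcomp(arm1)
             + "".join(rng.choice(_AC, size=BUFFER_LEN)))
    genome[h - BUFFER_LEN:h - BUFFER_LEN + len(block)] = list(block)

    o = min(MIR_OFFSET, arm - MIR_LEN - 2)
    mir_s = h + o
    emitter.emit(mir_s, mir_s + MIR_LEN, "+", cfg.mir_depth)
    wobble = round(cfg.mir_depth * cfg.isomir_fraction)
    if cfg.isomir_wobble > 0 and wobble > 0:
        emitter.emit(mir_s + cfg.isomir_wobble,
                     mir_s + MIR_LEN + cfg.isomir_wobble, "+", wobble)
    star_count = max(1, round(cfg.mir_depth * cfg.mirstar_fraction))
    t_hi = Lint - 1 - (o + 2)
    t_lo = Lint - 1 - (o + 2 + MIR_LEN - 1)
    emitter.emit(h + t_lo, h + t_hi + 1, "+", star_count)
    return TruthRecord(host.chrom, h, h + Lint, "+", "mir", "positive")


def generate_dataset(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, reads BED and truth TSV; returns the paths."""
    ds = simulate_dataset(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "genome.fa"
    bed = out_dir / "reads.bed"
    truth = out_dir / "truth.tsv"
    with open(fasta, "w") as fh:
        for name, gs in ds.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(gs.seq), 60):
                fh.write(gs.seq[i:i + 60] + "\n")
    write_alignments_bed(ds.reads, bed)
    with open(truth, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tclass\texpected_verdict\t"
                 "expected_rejection_reason\n")
        for t in sorted(ds.truths, key=lambda t: (t.chrom, t.start, t.end)):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.strand}\t"
                     f"{t.locus_class}\t{t.expected_verdict}\t"
                     f"{t.expected_rejection_reason or '.'}\n")
    return {"genome": fasta, "reads": bed, "truth": truth}
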