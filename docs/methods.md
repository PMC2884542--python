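# Methods

## The prediction model

`mirloci` identifies microRNA loci from strand-aware, genome-aligned small
RNA-seq reads using a system of binary decisions derived from the biochemistry
of miRNA biogenesis, rather than probabilistic scoring. A pre-miRNA stem-loop
is processed at stereotyped positions, so a genuine locus can emit at most
five product species — miR, miR* (the opposite-arm partner), up to two moRs
(miRNA-offset RNAs immediately flanking miR and miR*), and the loop — with a
strongly skewed abundance hierarchy. The predictor asks whether the observed
read products at a candidate locus are geometrically and quantitatively
compatible with this machinery, then removes surviving false positives using
two genomic-context signals: the displacement of antisense products and the
density of non-miR read regions in the neighborhood.

### Pass 1: per-locus biogenesis tests

1. **Read regions.** Reads aligning to fewer than `max_seed_hits` (default 5)
   genomic sites are merged into maximal overlap-connected regions
   (strand-insensitively, since the antisense test needs both strands at one
   locus; bookended reads do not merge). Multi-hit reads are attached to
   regions afterwards but never seed them. Regions shorter than 160 nt that
   do not overlap a repeat or tRNA annotation are candidates; all regions,
   including rejected ones, are retained for neighborhood counting.
2. **Folding.** Up to three 150-nt windows per candidate (region centered,
   region at either window end) are folded on the strand carrying the
   majority of read counts. The production engine is ViennaRNA's MFE fold; a
   built-in maximum-base-pair dynamic program (canonical pairs A·U, G·C, G·U;
   minimum loop 3; N never pairs; deterministic leftmost-outermost
   tie-breaking) serves as a dependency-free baseline and as the reference
   for oracle tests. Each innermost helix becomes a hairpin whose arms extend
   outward through nested pairs; two adjacent hairpins separated by at most
   `merge_gap` (8 nt) unpaired bases under a common outer helix are merged
   into one "double loop" hairpin. The hairpin with the most read-covered
   paired bases wins (ties: more stem pairs, then leftmost).
3. **Products.** The locus is the chosen hairpin's genomic span; all reads
   overlapping it — which typically spans several read regions, because miR,
   miR* and moRs need not overlap each other — are grouped greedily by
   descending count into products whose 5' ends agree within `group_radius`
   (3 nt, tolerating isomiR wobble without merging miR and moR). Products
   are classified by strict base-majority zone (5p arm / loop / 3p arm /
   outside; exact straddles are `split`): the most abundant mostly-paired
   product per arm is that arm's miR; a product immediately distal to a miR
   (gap ≤ 5 nt) is its moR; excess arm products are `out`. Antisense
   products are grouped identically but never labeled — a real antisense miR
   is an independent locus, called by a second run on the opposite strand.
4. **Metrics and thresholds.** Each locus yields: hairpin length; total
   sense reads and parts-per-million of the pooled library; the top miR
   product's read and distinct-variant counts; 5' heterogeneity (fraction of
   the top miR product's reads sharing the predominant variant's 5' end);
   minimum base-pairs-per-nucleotide over miR and miR*; same-arm 5' offsets
   (products overlapping ≥ 2 nt); the opposite-arm offset after projecting
   the 3p product through the pair table onto the 5p arm (a canonical Dicer
   duplex with 2-nt 3' overhangs projects 2 nt inside the 5p miR; a
   projection missing the 5p product returns a sentinel); the miR–moR gap;
   the count-weighted mean genome-hit number of the top miR product; and the
   AAPD (below). Every metric is compared against a named, user-configurable
   threshold; all failed filters are reported.

### Antisense product displacement (AAPD)

Authentic miR loci either lack antisense reads or carry antisense products
that coincide exactly with the sense products (bidirectionally transcribed
hairpin loci), whereas endo-siRNA/piRNA-like processing yields antisense
products offset by several nucleotides. For every sense/antisense product
pair whose predominant variants overlap by ≥ 1 nt, the displacement is the
absolute offset of the two products in genomic coordinates — the sense
product's 5' end against the antisense product's 3' end, the two ends that
coincide in a perfectly matched duplex. AAPD is the mean over all such
pairs and 0 when no pair overlaps: absence of antisense evidence never
penalizes a locus. The default threshold is 0 (exact coincidence required).

### Pass 2: non-miR neighborhood density

miR hairpins sit in genomic regions largely devoid of other small-RNA
production. For each provisional positive, the non-miR-neighbor-count is the
number of read regions (all of them, including repeat/tRNA and over-length
regions) intersecting a ±1 kb window that do not overlap any pass-1 positive
locus; the locus's own region is excluded. Loci with more than 10 such
neighbors are rejected. Pass 2 runs once against the pass-1 provisional set,
so tandem miR clusters — whose neighbors are themselves positive loci —
never reject each other.

Because several read regions can converge on the same (or a nearly
identical) hairpin, overlapping same-strand locus records are collapsed to
the best-supported one (most locus reads, then longer hairpin, then
leftmost) before evaluation.

## Thresholds

| name | default | comparison | anchoring |
|---|---|---|---|
| min_hairpin_length | 20 nt | ≥ | hairpins "20 nucleotides or longer" |
| min_locus_reads | 5 | ≥ | locus total "at least five reads" |
| min_locus_ppm | 1.0 | ≥ | "at least one part per million" of pooled reads |
| min_top_product_reads | 1 | strictly > | top miR product "more than one read" |
| max_aapd | 0 nt | ≤ | authentic loci have AAPD 0 |
| max_non_mir_neighbors | 10 | ≤ | known loci have ≤ 10 non-miR neighbors |
| min_five_prime_het | 0.33 | ≥ | package default, configurable |
| min_bp_per_nt | 0.55 | ≥ | package default, configurable |
| max_same_arm_offset | 3 nt | ≤ | package default, configurable |
| max_opposite_arm_offset | 5 nt | ≤ | package default, configurable |
| max_mir_mor_gap | 5 nt | ≤ | moRs are immediately adjacent; configurable |
| max_avg_genome_hits | 2.0 | ≤ | package default, configurable |

The last six defaults are design choices of this package (the decision rule
is deliberately threshold-parameterized); all of them round-trip through the
YAML config (`mirloci dump-config`). Classification parameters
(`group_radius`, `mor_gap`, `merge_gap`, `window_size`) are structural and
kept separate from the thresholds so that tightening any threshold can only
shrink the prediction set — a property the test suite sweeps explicitly.

## The synthetic-data generator

`mirloci.simulate` plants loci with known ground truth on a random genome:

* **miR loci** — perfect inverted repeats (30-bp stem, 6-nt loop; stems are
  rejected if they contain homopolymer runs of 4, so the planted register is
  the unambiguous fold) emitting miR (depth 100), 5'-wobbled isomiRs (10% at
  +1 nt), miR* at the stem-projected position with a canonical 2-nt 3'
  overhang (2% of depth), and a moR immediately upstream (1%); loop reads
  default to 0.0076% of depth and therefore to zero at default depth. This
  miR:miR*:moR:loop hierarchy mirrors the strong skew observed in real
  libraries.
* **siRNA decoys** — the same structurally valid locus plus antisense reads
  whose 5' ends are shifted 8 nt (the center of the displacement distribution
  seen at non-miR loci), at 50% of the miR depth. Setting the offset to 0
  turns decoys into antisense-bearing miR loci and the truth table marks them
  positive-eligible.
* **degradation patches** — a valid hairpin surrounded by 12 scattered
  single-read regions placed 330–970 nt to either side, so the locus passes
  every pass-1 filter and is rejected only by the neighborhood count.
* **background** — single reads placed uniformly at 0.2 reads/kb but
  rejection-sampled to stay > 1.1 kb from planted loci, so planted truth
  labels remain exact by construction.

Each planted hairpin carries 25-nt A/C-only buffers (A and C cannot
base-pair with each other), emulating the weakly structured flanks of real
pri-miRNAs. `plant_mirtron` places a hairpin that exactly fills a short
intron (the 58–70 nt mirtron range) and emits miR/miR* without moRs, since
mirtrons bypass the Drosha step that produces them.

What the generator does **not** emulate: sequencing errors, adapter
contamination, quality scores, multi-mapping reads at planted loci, imperfect
stems beyond the isomiR wobble, and expression differences across libraries.
Passing the planted-recovery tests therefore demonstrates the correctness of
the decision logic under clean, well-separated signals — not calibrated
performance on real libraries, where alternative secondary structures and
spurious reads are the dominant failure modes.

## Numerical and procedural choices

* Internal coordinates are 0-based half-open everywhere; GFF3 is converted at
  the boundary. Output ordering and float formatting are fixed, so identical
  inputs give byte-identical outputs.
* Predominant-variant ties resolve to the leftmost start, then the shortest
  span. The baseline folder breaks ties by pairing the leftmost available 5'
  base with the rightmost admissible partner, recursively.
* Pooled library size for ppm is the sum of collapsed read counts over all
  input alignments.
* Absent optional evidence passes vacuously: no antisense products → AAPD 0;
  no miR* → no opposite-arm test; no moR → no miR–moR gap test.
* Default problem sizes in the test suite (100-kb genome, 35 planted loci,
  1000-instance oracle comparisons) keep a full run within a couple of
  minutes on one core while exercising every locus class.

## Known limitations

* One hairpin is evaluated per candidate; a region containing two genuinely
  distinct overlapping hairpins yields only the better-covered one.
* The opposite-arm projection uses the 5'-most stem partner of the 3p
  product; in heavily bulged stems this can differ by the bulge width from
  the Dicer-duplex register.
* ppm normalization pools all libraries; per-library counts are reported in
  the TSV but no per-library threshold is applied.
* The family assignment compares matures 5'-anchored and ungapped over the
  shorter length; indel-containing family members are not matched.
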