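# mirloci

Rule-based prediction of microRNA loci from strand-aware small RNA-seq read
alignments.

Deep sequencing of small RNA libraries recovers not only microRNAs but also
endogenous siRNAs, piRNAs and mRNA degradation products, and many genomic
sequences fold into miR-like hairpins by chance. `mirloci` separates genuine
miRNA genes from these confounders with a system of **binary decisions**
grounded in the biochemistry of miRNA biogenesis, for people analyzing small
RNA-seq data in organisms where homology-based annotation is weak.

A candidate locus passes only if all of the following hold:

* its reads fall on a hairpin **≥ 20 nt** long;
* the products occupy the stereotyped miR / miR* / moR / loop positions on
  the hairpin — adjacent on the same arm, and shifted by only a small offset
  (≈ 2 nt, the Dicer-duplex 3' overhang) after projecting the 3p product
  through the stem's pair table onto the 5p arm;
* the locus carries **≥ 1 read per million** of the pooled library and
  **≥ 5 reads** total, and its top miR product has **more than one** read;
* its **AAPD** (average antisense product displacement — the mean offset
  between overlapping sense and antisense products) is 0: authentic loci
  either lack antisense reads or carry antisense products that coincide
  exactly with the sense products, while siRNA/piRNA-like loci show offsets
  of several nucleotides;
* in a second pass, its **non-miR-neighbor-count** — read regions within
  ±1 kb that do not overlap any predicted miR locus — is ≤ 10, rejecting
  hairpins embedded in degradation-rich neighborhoods without breaking up
  genuine tandem miR clusters.

Every threshold is user-configurable (`mirloci dump-config`); all failed
filters are reported per locus, not just the first. Folding uses ViennaRNA
when available, with a built-in maximum-base-pair folder as a deterministic
fallback. The package also contains a seeded synthetic-data generator that
plants miR loci, siRNA-like decoys and degradation patches with a per-locus
truth table — see `docs/methods.md` for the model, the generator's realism
envelope and all numerical choices.

## Worked example

Generate a small synthetic dataset (3 planted miRs, 2 siRNA decoys, 1
degradation patch on 20 kb) and predict:

```sh
mirloci simulate --out demo/data --seed 7 --genome-length 20000 \
    --n-mir-loci 3 --n-decoys 2 --n-patches 1
mirloci predict --genome demo/data/genome.fa --reads demo/data/reads.bed \
    --out demo/out
```

which prints:

```
mirloci 0.1.0 predict
libraries: reads
alignments loaded: 42 (skipped 0)
candidate loci evaluated: 21
positive predictions: 3
rejections by reason: antisense_displacement=2, few_reads=15, hairpin_too_short=2,
low_pairing=1, neighbor_count=1, no_mir_product=8, top_product_single_read=7
```

All 3 planted miRs are recovered; both decoys fail with
`antisense_displacement` (their antisense products sit 8 nt off the sense
products, so AAPD = 8) and the degradation-flanked hairpin fails only in
pass 2 with `neighbor_count`. The remaining rejections are the scattered
single-read degradation regions. `demo/out/predictions.gff3` holds one
`miRNA_primary_transcript` feature per positive locus with its labeled
products as children:

```
chrSim  mirloci  miRNA_primary_transcript  1667  1732  .  +  .  ID=mirlocus_0001;reads=113
chrSim  mirloci  ncRNA                     1648  1669  .  +  .  ID=mirlocus_0001.1;Parent=mirlocus_0001;label=5p-moR;reads=1
chrSim  mirloci  miRNA                     1671  1692  .  +  .  ID=mirlocus_0001.2;Parent=mirlocus_0001;label=5p-miR;reads=110
chrSim  mirloci  miRNA                     1705  1726  .  +  .  ID=mirlocus_0001.3;Parent=mirlocus_0001;label=3p-miR;reads=2
```

and `predictions.tsv` has one row per candidate with every metric, e.g.
(selected columns):

```
chrom   start  end    verdict   reasons                  hairpin_length  total_locus_reads  aapd
chrSim  1666   1732   positive  .                        66              113                0
chrSim  4999   5065   rejected  antisense_displacement   66              113                8
```

Positive predictions can then be assigned to known families by seed identity
(mature nucleotides 2–7) plus ≤ 4 mature mismatches:

```sh
mirloci family --predictions demo/out/predictions.tsv \
    --reference known_matures.fa --out demo/out/families.tsv
```

The same pipeline is available as a library:

```python
from mirloci import load_genome, load_alignments, two_pass_predict

genome = load_genome("demo/data/genome.fa")
reads, _ = load_alignments("demo/data/reads.bed", genome=genome)
records = two_pass_predict(reads, genome)
positives = [r for r in records if r.verdict == "positive"]
```

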