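# Methods

## Assay model

The pipeline assumes truncation-based CLIP chemistry on a defined
substrate: each cDNA begins one nucleotide 3′ of the crosslinked residue,
so the crosslink site is **alignment start − 1** (0-based). Libraries are
stranded; reads derive from a small custom transcriptome — one pre-mRNA
substrate (exon1–intron–exon2 with branch-point adenosine *brA*), the
five spliceosomal snRNAs, a spliced-mRNA reference derived as
exon1 ⧺ exon2, and endogenous background RNA represented by a decoy
reference set. All internal coordinates are 0-based half-open; SAM output
is 1-based; bedGraph stays 0-based half-open. Sequences are held in the
DNA alphabet, converting from RNA at the I/O boundary.

Relative coordinates: anchored on the brA, the brA itself is 0; anchored
on the 3′ splice site, the last intron nucleotide is 0 and the first
exon2 nucleotide is +1 (so "+10 downstream of the exon–exon junction"
is the tenth exon2 nucleotide).

## Mapping contract

Placements are end-to-end (pure-match CIGAR; no soft clips or indels,
which would shift the apparent truncation site) on the forward strand
only, with at most `max_mismatches = 2` Hamming mismatches. A read is
kept only when one placement has strictly the fewest mismatches across
all references; ties are discarded as ambiguous. The contract is *defined*
by a brute-force scan over every offset of every reference; the
production aligner (exact-substring fast path + vectorised mismatch
counting) is required by the test suite to agree with that brute force on
every read, so any seeding shortcut must be lossless.

One deliberate refinement: a read that matches the substrate and the
derived mRNA equally well *because it lies entirely within one exon* is
resolved to the substrate and flagged `exonic_shared`, avoiding double
counting while keeping junction sensitivity; such reads are never counted
as junction evidence. Reads unmapped against the custom transcriptome are
aligned to the background set; background hits enter the normalization
denominator (deduplicated like the signal) but are never profiled.

## Deduplication

PCR duplicates collapse by (sample, reference, start, UMI). `exact` mode
(the default, recorded in output metadata) keeps one cDNA per distinct
key. `directional` mode additionally merges, within one position, a UMI
*v* into a higher-count neighbour *u* when Hamming(u, v) = 1 and
count(u) ≥ 2·count(v) − 1, absorbing amplification/sequencing-error UMIs.
Both modes are idempotent. Note an intrinsic limit: with a 5-nt UMI,
positions receiving ≫1024 cDNAs saturate the UMI space and distinct
molecules sharing a UMI at one position are indistinguishable in
principle; truth-scoring therefore compares against distinct
(reference, position, UMI) triples.

## Substrate filters

* **Branch-point mask**: counts at brA − 2 … brA + 2 (5 positions,
  clipped at reference bounds) are zeroed and logged. Residual
  truncations at partially digested three-way lariat junctions truncate
  at the brA and would otherwise read as crosslinks. The filter removes
  cDNAs whose *crosslink site* falls in the window (a truncation artifact
  manifests at the cDNA start), not reads merely overlapping it.
* **Intron removal** (for mRNA-bound, post-exon-ligation complexes):
  intronic counts zeroed, exonic counts untouched. The two filters
  commute.
* **Junction reads**: a read is junction-spanning iff it maps uniquely to
  the derived mRNA with ≥ 5 aligned nt on each side of the junction; the
  reported fraction is over reads uniquely mapped to the custom
  transcriptome (background hits excluded from the denominator).

## Normalization, subtraction, smoothing

Every library also captures endogenous RNA, so the background-mapping
cDNA count acts like a spike-in: values are counts × 10⁶ / background
cDNAs. Control libraries (no tag, or no UV) are subtracted pointwise;
negative values are retained and flagged for plotting/export but excluded
from peak calling and weighted summaries.

Smoothing uses a discrete Gaussian with window *w* = 10 nt by default
(matching the ~9 nt of RNA spanned by a DEAH-box helicase's two RecA
domains): σ = w/4, support truncated at ±w/2, kernel normalized to sum 1.
At the boundaries each *source* position's clipped kernel is renormalized
to sum 1 before redistribution (`out = conv(v/Z, k)` with
`Z = conv(1, k)`), the one choice that conserves total signal mass
exactly everywhere; a constant profile is unchanged at interior positions
(beyond 2·⌊w/2⌋ from an edge). The tail weight of this kernel is a
declared convention — other smoothers with the same nominal window may
weight tails differently.

## Summaries and statistics

* **Species proportions**: deduplicated cDNA shares per reference;
  replicate sets may be summed first (equivalent to concatenating
  libraries).
* **snRNA enrichment**: per-snRNA counts (+ pseudocount 1) are first
  normalized to the total snRNA crosslinks within each sample; the
  reported value is log₂(f_tagged / f_untagged). Because of this
  within-sample renormalization, a *k*-fold rate change reads out as
  log₂ *k* only when the snRNA totals of the two conditions match; the
  bundled enrichment conditions are constructed accordingly (see below).
* **Weighted position summary**: box statistics of crosslink positions
  weighted by signal. Quantiles are inverted-CDF (smallest position whose
  cumulative weight fraction reaches *q*): this step-function convention
  is exactly invariant under rescaling all weights and exactly equals
  ordinary `inverted_cdf` quantiles of the weight-expanded sample for
  integer weights — properties no interpolating weighted quantile has
  simultaneously. Whiskers end at the most extreme weighted positions
  within 1.5·IQR of the box; weighted positions beyond are outliers.
* **Peak detection**: arg-max over strictly positive, unmasked values in
  a region, ties to the smallest coordinate, reported relative to brA or
  the 3′-SS; all-non-positive regions yield "no peak".
* **Peak comparison**: Student's unpaired two-sided pooled-variance
  t test on per-replicate main-peak positions (df = n₁ + n₂ − 2). Zero
  pooled variance is handled explicitly (equal means → t = 0, p = 1;
  unequal → p → 0, flagged degenerate).

## Synthetic libraries

The generator emulates, per emitted read: species choice (substrate vs
each snRNA) by relative crosslink propensity; for substrate templates a
molecule class — intact pre-mRNA, lariat intermediate (positions
restricted to intron + exon2), or spliced mRNA (reads drawn on the
derived reference so junction reads arise naturally); crosslink sites
from a mixture of Gaussian/uniform components anchored on the brA or
3′-SS (crosslinks for mRNA molecules follow the model restricted to
exons, falling back to uniform when the model is wholly intronic); a
uniform non-specific floor; branch-point artifacts (a lariat cDNA
truncates at the brA with probability `branch_artifact_rate`, default
0.05); background templates from the decoy set; fragment lengths from a
truncated geometric (20–60 nt, mean 35, emulating controlled RNase
digestion); the barcode/UMI layout prefix and 3′ adapter; geometric PCR
copy numbers (mean 2) sharing the UMI; and uniform per-base substitution
errors (10⁻³). One seeded generator drives everything, so reruns are
byte-identical and every read has exactly one ground-truth row.

What it does **not** model: base-quality-dependent errors, crosslink
nucleotide preference (the uridine bias of UV crosslinking), ligation
biases, structured RNA effects, or a genome-scale background — so
passing tests demonstrate the pipeline's correctness on its own
assumptions, not robustness to every bias of real libraries. The no-UV
control is modelled identically to no-tag (background + floor).

## Bundled study conditions

`spliceclip.experiments` fixes one set of realistic conditions used by
the test suite and `scripts/acceptance.py`:

* a 620-nt substrate (120 exon1 / 380 intron / 120 exon2, brA 39 nt
  upstream of the 3′-SS, ACT1-like geometry) with the five snRNAs at
  their natural yeast lengths and two 1.5-kb background decoys;
* a Prp16-like model: one Gaussian at brA + 20 (sd 3), substrate/snRNA
  propensity 0.7/0.3, 15% background, 2% non-specific floor; controls are
  90% background;
* peak-recovery runs at 50,000 reads with a 10,000-read no-tag control,
  20 seeds;
* junction runs: 12% spliced-mRNA molecule mix, duplicate-free (so
  junction counts are binomial over independent templates), compared to a
  closed-form expectation from fragment-length and junction-coverage
  geometry;
* enrichment runs: the untagged floor touches all five snRNAs (shares
  .15/.05/.15/.05/.60 for U1/U2/U4/U5/U6); the tagged catalytic-stage
  complex has released U1/U4 (they leave the spliceosome before the C
  complex forms), binds U2/U5 at 4× their floor rate and U6 unchanged.
  The U2/U5 gain offsets the U1/U4 loss, so snRNA totals match across
  conditions and the designed log₂ fold changes are exactly +2 (U2/U5),
  0 (U6), and strongly negative (U1/U4).

Problem sizes (10–50 k reads, ≤ 3 kb of custom reference, 20 seeds) are
the package's desk-scale defaults: large enough for tight binomial
checks, small enough that the whole suite runs in minutes on one CPU.

## Known limitations

* The aligner scans a bounded decoy background, not a full genome;
  scale-up would need an indexed external aligner via `ingest_sam`.
* Exactly one substrate per run; no general gene models.
* UMI saturation at very deep single-position peaks (above) biases
  absolute cDNA counts downward; peak *positions* are unaffected.
* The directional-dedup count-skew threshold assumes error UMIs are much
  rarer than their parents, as in standard CLIP practice.
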