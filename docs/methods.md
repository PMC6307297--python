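# Methods

## Coordinate model and distances

All coordinates are internally 0-based, half-open `[start, end)`; GTF I/O
converts to and from the 1-based inclusive file convention at the boundary.
The TSS of a transcript is `span.start` on `+` and `span.end` on `-`. A gene's
span is the union envelope of its transcripts' spans, and a gene keeps one TSS
per distinct transcript start, so promoter tests quantify over alternative
promoters.

The distance from a point to a gene span is the coordinate gap to the nearest
base contained in the span (0 if the point lies inside). This makes the two
flanks symmetric: a point one base left of the first base and one base right
of the last base both have distance 1. Nearest-gene ties are broken by smaller
distance, then lexicographic gene id, and the bisection/interval-tree index is
tested to agree exactly with an exhaustive scan.

Two distance modes are supported for the nearest-neighbor analysis: gap to the
gene body (default — the comparison is against whole genes, not promoters) and
gap to the nearest coding TSS (`distance_mode="tss"`). By default the neighbor
pool is restricted to protein-coding genes expressed (fpkm ≥ 1) in at least
one ventricle stage.

## Filtering cascade

- **Spliced**: exon count ≥ 2 (`min_exons`). Mono-exonic models are too often
  assembly artifacts or fragments to be trusted without very high coverage.
- **Non-coding**: transcripts whose biotype marks them as known mRNA or small
  functional RNA (snoRNA, tRNA, other annotated non-lncRNA classes) are
  removed, as is any transcript with annotated CDS longer than 1/3 of its
  length (`cds_fraction_max`); the removal is strict (`>`), so a CDS of
  exactly one third is retained. No sequence-based coding-potential prediction
  is attempted — the rule uses annotation-declared CDS only.
- **Expressed**: fpkm ≥ 1 (`min_fpkm`, inclusive) in at least one heart-stage
  sample. 1 fpkm is where transcript models become reliably reconstructable
  (see the QC fit below).
- **Selective**: expressed in the heart as above and below the same threshold
  in *every* reference-tissue (brain) sample. The same single threshold is
  used for "expressed" and "not expressed" for symmetry; both are
  configurable. Requiring silence in all reference samples (rather than any
  pooling) is the stricter, simpler choice. A census against extra tissues
  (kidney, liver) uses the same threshold.

Filtering is transcript-level throughout; gene-level summaries take the
maximum over isoforms. All filters are pure set intersections — the pipeline
order is a presentation choice, and the tests assert order-invariance and
monotonicity in the thresholds.

## Context classification

- **Bidirectional**: some protein-coding TSS on the opposite strand within
  `bidirectional_window` = 3,000 bp of the candidate TSS, with the pair in
  head-to-head divergent orientation (the `+` partner at or to the right of
  the `-` partner). The window alone would also capture convergent pairs, but
  a bidirectional promoter fires outward in both directions, so divergence is
  required by default (`require_divergent`); same-strand proximity is recorded
  as a diagnostic flag only. The TSS gap is the unstranded absolute
  difference.
- **Antisense**: candidate span overlaps a protein-coding *gene span* on the
  opposite strand by ≥ 1 bp. Gene-span (not exon) overlap is used because the
  motivating geometry is a lncRNA lying wholly within an intron of the host.
- **Both** when a candidate qualifies for each (possibly via different
  isoforms of the same gene); otherwise **intergenic**.
- **Orientation census**: among candidates whose TSS lies within
  `proximity_window` = 10,000 bp of a known (non-candidate) gene, count
  opposite-strand vs same-strand relative to the nearest such gene. Comparing
  with the single nearest gene is the default; `mode="any"` instead asks
  whether any gene in the window is opposite.

The exact symmetry of the classifier is a mirror image — flipping every strand
*and* reflecting coordinates — under which every candidate keeps its label;
this is tested. A bare strand flip is not a symmetry, because the TSS moves to
the opposite span boundary.

## Statistics

- **Mann-Whitney U** (distance comparisons): exact null enumeration when
  n₁+n₂ ≤ 16 with no ties, otherwise the normal approximation with tie and
  continuity corrections; two-sided throughout. The exact path is verified
  against a full labeling enumeration, and the approximation agrees with the
  exact p within 0.02 at n = 8 per group.
- **Hypergeometric enrichment**: upper tail P(X ≥ k), since
  over-representation is the direction of interest. The tail is summed exactly
  over big integers (via the pmf's multiplicative recurrence) for populations
  up to 10⁵ and in log space (gammaln + logsumexp) beyond that or when the
  exact value underflows. Odds ratios come from the implied 2×2 table with a
  Haldane 0.5 correction when a cell is empty. A gene "has a bidirectional
  lncRNA" if any of its isoform TSSs has a qualifying divergent candidate.
- **Housekeeping control**: Fisher's exact two-sided test of
  housekeeping × haploinsufficient, guarding against the enrichment being an
  artifact of broad-expression confounding.
- **Gene-set over-representation**: one hypergeometric tail per term against a
  fixed universe, Benjamini-Hochberg adjusted across the terms of one
  analysis only (no cross-analysis correction), sorted by raw p.
- **Pair correlation**: Pearson r on log2(fpkm + 1) per divergent pair across
  the heart stages, replicates averaged per stage first. The pseudocount of
  1.0 handles zeros and is configurable. With only three developmental stages
  r is a coarse, sign-oriented summary; pairs with zero variance in either
  log-series are flagged undefined and excluded from the histogram.
- **Localization ratio**: log10((intact + pc)/(nuclear + pc)) per transcript;
  positive = cytoplasm-skewed, negative = nucleus-skewed.
- **Assembly-fidelity QC**: per gene (matched by id), exon number is the
  maximum over alternative transcripts; genes with reference exon number > 12
  are excluded (the long tail would dominate the difference scale). The
  difference |assembled − reference| is fit with a·exp(−b·fpkm) by
  least squares on stage-max fpkm. A decaying exponential is the natural
  shape — reconstruction error shrinks as coverage rises — though the precise
  functional family is a modeling choice. The fit also reports the fpkm at
  which the expected difference drops below 0.5 exons (the coverage needed to
  get exon structure right on average). All-zero differences make the decay
  unidentifiable; that case is flagged rather than fit.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, not
sequencing itself (no reads, no sequences, no mapping biases):

- **Layout**: coding genes (12–18 kb, 4–9 exons, CDS ≈ 25% of exonic length)
  on a fixed locus grid (80 kb spacing) across `n_chroms` chromosomes; the
  grid guarantees that planted classes cannot collide. Bidirectional lncRNAs
  are placed divergently with a TSS gap drawn from 100–2,700 bp; antisense
  lncRNAs sit inside the host gene body with their TSS 6 kb from the host
  promoter; intergenic lncRNAs go into inter-locus gaps with ≥ 20 kb clearance.
  Every planted locus keeps a ≥ 10% margin from each decision boundary
  (3,000 bp window, 10,000 bp census window, 20 kb intergenic clearance), so
  label recovery is deterministic rather than flaky. All lncRNAs are spliced
  (2–4 exons) with zero CDS.
- **Expression**: lognormal-style noise on the log2 scale. Coding genes center
  near 20 fpkm; lncRNA heart fpkm is drawn from ≈1.2–8 fpkm (lower than
  coding, and tissue-selective lncRNAs essentially never exceed 10 fpkm).
  Heart-selective lncRNAs are below 1 fpkm in every brain sample;
  non-selective ones are expressed in brain. Divergent partners follow
  `log2 y = intercept + sign · strength · log2 x + noise` across the three
  heart stages (defaults: strength 0.9, noise SD 0.2, sign ± with equal
  probability), so the correlation analysis sees n = 3 points per pair — the
  developmental axis of the study design.
- **Labels**: haploinsufficiency is planted with baseline odds solved
  numerically so the marginal HI fraction equals `hi_fraction` (default 10%)
  while bidirectional carriers get odds multiplied by `hi_bidirectional_odds`
  (default 3). Housekeeping flags are independent Bernoulli(0.3) draws — the
  null the control test should not reject. A label-level generator
  (`simulate_label_table`) supports the calibration/power simulations without
  genome placement.
- **Randomness**: one RNG stream per sub-generator (placement, selectivity,
  expression, labels) spawned from the master seed, so enlarging one stage
  never reshuffles another; identical config + seed reproduces byte-identical
  output files.
- **QC emulation** (`simulate_exon_truncation`): drops terminal exons per gene
  with Poisson(a·exp(−b·fpkm)) counts, truncated so one exon survives, giving
  a known generating curve for the QC fit to recover.

What passing on synthetic data does *not* show: robustness to assembly
artifacts, fragmented or chimeric models, overlapping gene clusters, unstranded
libraries, replicate-level biological noise, or annotation errors — the
generator's geometry is deliberately clean so that logic errors, not data
pathology, are what the tests detect.

## Problem sizes and numerical choices

The default simulated study is 200 coding genes with 20/20/20 planted lncRNA
classes and two-thirds heart selectivity — large enough that every census and
distance summary is non-trivial, small enough that the full pipeline runs in
seconds. Calibration uses 200 seeds and power 100 seeds at 2,000 genes; the
correlation check uses 100 pairs; the QC recovery uses 500 genes. The
acceptance script reports each quantity with the n it was computed on.

Ties in nearest-gene queries resolve by (distance, gene id); BH uses the
standard step-up with running minimum; the exact Mann-Whitney path is limited
to 16 combined observations (12,870 labelings at worst); curve fitting starts
from (max difference, 0.1) with non-negative bounds.

## Known limitations

- Coding potential relies entirely on annotated CDS; novel ORFs are unseen.
- The classifier treats annotation as truth: no attempt to merge fragmented
  transcript models or detect run-through transcription.
- With three developmental stages, pair correlations are sign-indicative
  only; confidence intervals on r would be vacuous at n = 3 and are not
  reported.
- The orientation census defaults to the nearest known gene; in dense loci
  the `any`-gene-in-window variant can differ.
- Gene-set enrichment is a plain hypergeometric over-representation test; it
  does not model annotation hierarchy (no GO DAG propagation) or
  database-specific score modifications.
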