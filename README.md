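# heartlnc

Identification and genomic-context classification of spliced, tissue-selective
long non-coding RNAs (lncRNAs) from assembled transcript models, together with
the downstream statistics used to characterize them: nearest-gene distance
comparisons, divergent-pair expression correlation across development, and
hypergeometric enrichment of bidirectional-lncRNA-bearing genes among
dosage-sensitive (haploinsufficient) genes.

The package is aimed at transcriptomics analysts who have assembled transcript
models (GTF) and a transcript × sample fpkm matrix for a tissue of interest
(here: heart ventricle across development) plus reference tissues, and who want
a reproducible, tested version of the standard "find tissue-selective spliced
lncRNAs and ask what they sit next to" analysis.

## What it computes

**Candidate identification** (filtering cascade, all pure set intersections):

1. keep spliced transcripts (≥ 2 exons);
2. drop annotated mRNAs and small functional RNAs (snoRNA, tRNA, …) and any
   transcript whose annotated CDS covers more than 1/3 of its length;
3. require fpkm ≥ 1 in at least one heart stage;
4. call **heart-selective** transcripts: expressed in the heart but below
   threshold in every brain sample, with a kidney/liver expression census.

**Genomic context** relative to protein-coding genes:

- **bidirectional**: some coding TSS on the opposite strand lies within
  3,000 bp of the lncRNA TSS and the pair is head-to-head divergent;
- **antisense**: the lncRNA span overlaps a coding gene span on the opposite
  strand (intronic overlap counts);
- **both** when the two co-occur (e.g. via alternative promoter isoforms);
  otherwise **intergenic**.

**Statistics**:

- nearest-gene distances from each lncRNA TSS (expressed neighbors only, by
  default) and Mann-Whitney U comparisons of the distance distributions
  (mRNA vs all lncRNA vs heart-selective lncRNA);
- an orientation census of lncRNAs within 10 kb of known genes (opposite vs
  same strand);
- Pearson correlation of log2(fpkm + 1) between divergent pairs across the
  heart stages;
- hypergeometric upper-tail enrichment P(X ≥ k) of bidirectional-lncRNA-bearing
  genes among haploinsufficient genes, with a housekeeping-gene Fisher control
  and a generic BH-corrected gene-set over-representation test;
- an assembly-fidelity QC that fits the per-gene exon-number difference against
  expression with a decaying exponential a·exp(−b·fpkm).

Because raw sequencing data for this kind of study is often unavailable, the
package ships a first-class synthetic-data generator that plants all of the
structure above (classes with geometric safety margins, selectivity, signed
expression coupling, enrichment odds) so every pipeline stage can be validated
against known ground truth.

## Worked example

Simulate a bundle (200 coding genes; 20 bidirectional, 20 antisense,
20 intergenic lncRNAs; two thirds heart-selective) and run the full pipeline:

```bash
heartlnc simulate --seed 42 --outdir demo
heartlnc run --config demo/run_config.yaml
heartlnc report --rundir demo/results
```

The run prints (abridged from `demo/results/report.json`):

```json
{
 "n_candidates": 60,
 "n_heart_selective": 40,
 "class_counts": {"antisense": 20, "bidirectional": 20, "intergenic": 20},
 "orientation_census": {"opposite": 40, "same": 0},
 "distance_summary": {
   "median_mrna": 65434.5,
   "median_all_lnc": 1008.0,
   "median_selective_lnc": 1540.5,
   "p_selective_vs_mrna": 1.89e-23
 },
 "enrichment": {
   "hi_enrichment": {"N": 200, "K": 20, "n": 14, "k": 5,
                     "odds_ratio": 6.33, "tail_p": 0.0067},
   "housekeeping_control_p": 0.525
 }
}
```

Reading: all 60 planted lncRNAs survive the cascade, 40 are called
heart-selective (exactly the planted set), every genomic-context label matches
its planted class, and all 40 lncRNAs near genes run opposite to them (the
generator plants bidirectional and antisense loci only on the opposite strand).
The planted association between carrying a bidirectional lncRNA and the
haploinsufficient label is detected (upper-tail hypergeometric p = 0.0067 at
this small gene count) while the independent housekeeping flags show no
association (Fisher p = 0.53). Distances here reflect the synthetic layout, in
which partnered lncRNAs sit very close to coding genes and coding loci are
widely spaced.

The same steps are available as library calls (`heartlnc.pipeline.run_pipeline`,
`heartlnc.identify_candidates`, `heartlnc.classify_genomic_context`, …); the
CLI is a thin wrapper. Individual subcommands (`identify`, `classify`,
`correlate`, `enrich`, `qc`) expose each stage separately.

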