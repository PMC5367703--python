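# callsig

Transcriptome-signature analysis for pre-B childhood acute
lymphoblastic leukemia (cALL) subtypes.

Pre-B cALL is stratified into molecular subtypes — high hyperdiploidy
(HeH, >50 chromosomes), t(12;21), t(9;22) and a heterogeneous "Other"
group — that differ in prognosis but are conventionally called by
karyotyping and fusion assays.  `callsig` implements, as a reusable and
tested library, the expression-based alternative: starting from a
gene-level count matrix and a clinical sample table it

* calls leukemia-wide and subtype-specific transcripts (protein-coding
  and lncRNA) with per-gene negative-binomial GLMs,
  `K_gs ~ NB(mu_gs, phi)`, `log mu_gs = offset_s + x_s' beta_g`,
  likelihood-ratio tests and per-contrast Benjamini–Hochberg FDR;
* classifies tumour subtype with leave-one-out 3-nearest-neighbour
  voting over Euclidean logCPM distances, repeated over 100 random
  50% gene subsamples and an incremental top-variance gene grid, with
  a class-balanced undersampling variant;
* quantifies the hyperdiploid gene-dosage effect by regressing each
  autosome's median HeH/control fold change on its mean copy number,
  and re-runs the distance/classification analyses with the frequently
  gained chromosomes (4, 6, 10, 14, 17, 18, 21) excluded;
* measures promoter bivalency (H3K4me3 + H3K27me3 within ±5 kb of the
  most upstream TSS) and TF-peak enrichment (hypergeometric) across
  dysregulation categories;
* groups genes into co-expression modules via soft-threshold adjacency
  `|cor|^6`, topological overlap, Ward clustering, eigengene merging,
  and correlates module eigengenes with subtype membership.

Because the archived cohort is not required, a first-class synthetic
cohort generator (`callsig.simulate`) produces counts, metadata, gene
models and peak tracks from a fully specified model with planted
ground truth; every analysis stage is validated against it.  A
transcription of the 56-patient cohort characteristics table is
packaged for parser-level checks.

## Worked example

```python
import numpy as np
from callsig import SimConfig, simulate_counts
from callsig import diffexp, dosage, classify
from callsig.expression import log_cpm, upper_quartile_factors

counts, samples, genes, truth = simulate_counts(SimConfig(seed=1))

models = diffexp.fit_nb_glm(counts, samples)          # NB GLM per gene
de = diffexp.de_table(models)                         # 4 subtype contrasts
calls = diffexp.call_dysregulation(de)
print("DETs:", int(calls["is_det"].sum()),
      "leukemia-wide:", int(calls["leukemia_status"].isin(["up", "down"]).sum()),
      "subtype-specific:", int((calls["specific_subtype"] != "none").sum()))

rep = dosage.dosage_regression(counts, samples, genes)
print(f"dosage: slope={rep.slope:.3f} r={rep.pearson_r:.3f}")

expr = log_cpm(counts, upper_quartile_factors(counts), prior_count=1.0)
tumor = samples.index[samples["group"] != "Control"]
acc = classify.accuracy_curve(expr[list(tumor)], samples.loc[tumor, "group"],
                              genes, gene_counts=(50,), replicates=25,
                              rng=np.random.default_rng(11))
print(f"KNN accuracy with 50 genes: {acc.overall.loc[50, 'mean']:.2f}")
```

prints

```
DETs: 397 leukemia-wide: 218 subtype-specific: 140
dosage: slope=0.437 r=0.986
KNN accuracy with 50 genes: 1.00
```

397 of 2000 simulated genes are significant (FDR <= 1e-3) in at least
one subtype-vs-control contrast, 218 concordantly in all four
("leukemia-wide") and 140 in exactly one ("subtype-specific") —
recovering the planted 15% + 8% structure.  The dosage slope of ~0.44
per copy (trisomy = 1.5x expression, compressed slightly by CPM
renormalisation) with r = 0.99 reproduces the linear gene-dosage
relationship, and 50 top-variance genes suffice for essentially
perfect subtype classification on this cohort.

A command-line interface mirrors the library
(`callsig --seed 7 --outdir out all`, or the individual stages
`simulate | de | classify | dosage | epigenome | modules`), writing
TSV result tables and a JSON run manifest with the config hash, seed
and per-stage timings.  Gene models are accepted as GTF or as a
BED-like dialect with columns
`chrom start end gene_id score strand biotype tss_list`.

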