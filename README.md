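# clonetrace

Clonal tracking and genomic dynamics of multi-organ metastasis in barcoded
patient-derived xenograft (PDX) models.

When tumor cells are labeled with a high-complexity lentiviral DNA barcode
library, engrafted into the mammary fat pad (MFP) of recipient mice, and
sequenced after metastatic outgrowth, each barcode marks a clonal lineage.
Comparing the barcode repertoires of a primary tumor and its metastases
measures how severe the metastatic bottleneck is, how many clones seed each
lesion, and how few come to dominate it. `clonetrace` implements that
analysis end to end, together with the companion genomic computations used
to validate it: single-hit limiting-dilution frequency estimation,
mutant-allele-frequency (MAF) dynamics between primary tumors and
metastases, and a robustness test for MCMC-derived mutation clusters.

## What it computes

**Barcode quantification** (`clonetrace.quantify`). Reads carry an 18 bp
half-barcode, the spacer `TTCG` at positions 19–22, and a second 18 bp
half-barcode. Reads pass if the spacer matches within Hamming distance 1;
each half must align uniquely to the half-barcode reference library,
tolerating one mismatch at a terminal base; surviving reads are counted as
barcode *pairs* and normalized per sample to counts per million:
CPM_i = Counts_i / ΣCounts × 10⁶.

**Clonal architecture** (`clonetrace.metrics`). Dominant barcodes (smallest
prefix of the CPM-ranked list reaching 95 % of the sample mass), Shannon
diversity H = −Σ p_i ln p_i (nats), seeding clones (barcodes detected in
both a metastasis and its matched MFP tumor), TIC frequency
(100 × tumor-unique / reference-unique barcodes), Jaccard overlap, Welch
t-tests between organ sites, and per-mouse max-CPM summaries.

**Limiting dilution** (`clonetrace.dilution`). Under the single-hit Poisson
model a transplant of *d* cells is positive with probability 1 − e^(−f·d).
The metastasis-initiating frequency f is the MLE of
Σ [ pos·ln(1 − e^(−f·d)) − f·d·neg ], with 95 % Wald intervals on log f
(profile-likelihood optional).

**Variant dynamics** (`clonetrace.variants`). Consensus variant filters for
WES and targeted deep sequencing; ΔMAF = mean MAF(metastases) − mean
MAF(primaries) with the |ΔMAF| ≥ 0.15, p ≤ 0.05 enrichment rule; de novo
mutation candidate criteria; a chi-square + Benjamini–Hochberg co-occurrence
filter for repeat-region alignment artifacts; the qPCR human-DNA fraction
100·2^(−ΔCt,h)/(2^(−ΔCt,h)+2^(−ΔCt,m)); Pearson/hierarchical sample
similarity.

**Cluster stability** (`clonetrace.stability`). From an MCMC trace of
variant-to-cluster assignments, the pairwise co-assignment probability
matrix is discretized (p < 0.5, 0.5 ≤ p < 0.9, 0.9 ≤ p ≤ 1) and each
candidate cluster's category counts are chi-square-tested against the
trace-wide baseline, Bonferroni-corrected; only robust clusters are kept.

**Synthetic experiments** (`clonetrace.synth`). A generator producing
ground-truth-annotated libraries, multi-mouse seeding experiments, reads,
variant tables and assignment traces, so every stage is testable without
access-controlled data.

## Worked example

Simulate one barcoded mouse (30,000 cells at MOI 0.2, 4 % engraftment,
lesions seeded by 100 clones with 5 dominant clones amplified 500-fold),
quantify and analyze it, and fit the bundled dilution tables:

```python
from clonetrace import pipeline
cfg = pipeline.RunConfig(seed=7, outdir="demo",
    simulate=pipeline.SimulateConfig(n_mice=1, n_lung=2, n_liver=1,
                                     reads_per_sample=20000))
pipeline.run_pipeline(cfg)
```

`demo/metrics/per_sample.tsv` then holds:

```
sample_id mouse  site  n_unique_barcodes  n_dominant  shannon_nats
    A_MFP     A   MFP                225         158      4.948416
  A_lung1     A  lung                111          49      2.519299
  A_lung2     A  lung                108          45      2.477730
 A_liver1     A liver                105          45      2.475058
```

The metastatic lesions show the expected bottleneck: fewer unique barcodes,
fewer dominant barcodes and sharply reduced Shannon diversity relative to
the primary MFP tumor. `demo/mif.json` holds the single-hit fits of the
bundled transplantation tables, e.g. a lung metastasis-initiating frequency
of 17.9 % (95 % CI 6.6–48.6 %) for the first model and 0.7 % (0.2–2.3 %)
for the second.

The same stages are available from the shell:

```
clonetrace run-all --seed 7 --out demo
clonetrace mif --assay dilution.csv
clonetrace stability --trace trace.tsv --burn-in 2500
```

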