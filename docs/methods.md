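# Methods

## Scope and data model

`clonetrace` analyses lineage-barcoded xenograft experiments. A clone is the
set of cells descended from one lentivirally barcoded ancestor; its label is
a *pair* of 18 bp half-barcodes flanking the spacer `TTCG`, so the label
space is the Cartesian product of two half-libraries. The package covers
five computations — barcode quantification, clonal-architecture metrics,
single-hit limiting-dilution estimation, variant (MAF) dynamics, and
mutation-cluster robustness — plus a synthetic-data generator that emulates
the experimental design so every stage has ground truth to test against.
Genome alignment, variant calling, copy-number estimation and the MCMC
clustering itself are upstream of this package: it consumes their outputs
(read-count tables, co-occurrence tables, assignment traces).

## Barcode quantification

Coordinates are 1-based inclusive. A 40 bp read passes the spacer filter iff
positions 19–22 are within Hamming distance 1 of `TTCG`; `N` counts as a
mismatch. Reads longer than 40 bp keep their first 40 bases (adapter
remnants); shorter reads are rejected per read. Halves (positions 1–18 and
23–40) are matched against the reference library by hash lookup: exact
match, else the six single-substitution variants at the first and last base.
The end-anchored tolerance reflects alignment parameters that allowed "1 bp
mismatch at either end"; because the exact aligner invocation is
under-specified, `mismatch_anywhere=True` relaxes the mismatch to any
position. A half is assigned only when exactly one library member attains
the minimal distance; ambiguous halves are discarded, never rescued. Only
reads with both halves uniquely assigned are counted, preserving the
pairing. CPM_i = Counts_i / ΣCounts × 10⁶ per sample; a sample with zero
surviving reads yields an all-zero CPM column with a warning flag rather
than NaNs.

With library min-distance ≥ 3 these rules make the matcher exact: a query
within the tolerance of one member cannot be within tolerance of another
unless both hits are distance-1, which the ambiguity rule handles. The test
suite checks the matcher against an exhaustive Hamming-scan oracle over
every single-substitution perturbation of every library member.

## Clonal metrics

*Dominant barcodes*: sort by CPM descending, ties broken by barcode id
ascending (stable, deterministic); return the smallest prefix whose
cumulative CPM reaches the threshold (default 0.95), including the crossing
barcode. The inclusive boundary is a choice — the published rule does not
say whether the crossing barcode is in or out — and `inclusive=False` gives
the alternative.

*Shannon diversity* is reported in nats over all detected barcodes.
*Seeding clones* are barcodes detected (≥ 1 read by default; the floor is
configurable for sensitivity analyses) in both a metastasis and the matched
MFP tumor of the same mouse; cross-mouse comparisons raise, since barcode
identity is meaningless between independently labeled animals, and a mouse
must have exactly one MFP sample for its metastases to be comparable.
*TIC frequency* = 100 × tumor-unique / reference-unique barcodes; values
over 100 % are reported with a warning rather than clipped.
*Group comparisons* use the Welch two-tailed t-test by default
(`equal_var=True` restores pooled-variance Student); the published analyses
say only "two-tailed T-tests", and Welch is the safer default under unequal
group sizes and variances. Percent-of-MFP denominators are the unique
barcodes detected in the matched MFP tumor.

## Single-hit limiting dilution

The model: a transplant of dose *d* cells is positive with probability
1 − e^(−f·d), where f is the frequency of cells able to initiate the read-out
(a metastasis, or a tumor). The log-likelihood over assay rows
(dose, tested, positive) is maximized on the log(f) scale by bounded scalar
minimization (xatol 1e−12), which tests verify against a 200,000-point
grid-search oracle and, as an independent route, against a binomial GLM with
complementary-log-log link and log-dose offset (whose intercept is exactly
log f̂ — the classical ELDA formulation). The default 95 % CI is Wald on
log f using the observed information (numeric second difference of the
log-likelihood, step 1e−5); `ci_method="profile"` gives the
likelihood-ratio interval. Degenerate assays are flagged: all-negative data
return only the 95 % upper bound ln 20 / Σ(d·tested); all-positive data
return f̂ at the upper boundary with a likelihood-based lower bound.
Estimates are displayed as percent to one decimal place, matching the
published table's precision. The bundled `TABLE1` constant carries the
published dose/tested/positive counts; the single-hit MLE reproduces the
printed lung (17.9 %) and brain (0.7 %) frequencies of the first model and
the lung frequency (0.7 %, closed form ln(29/14)/100) of the second, while
the printed liver value (2.1 %) is *not* the single-hit MLE of the printed
liver counts (1/3 at 100 cells, 2/3 at 10 cells give ≈ 1.2 %); the package
reports the MLE and does not silently reconcile the discrepancy.

`recover_from_simulation` validates the estimator by parametric bootstrap:
positives ~ Binomial(tested, 1 − e^(−f·d)), reporting mean bias and
empirical CI coverage over the estimable replicates (degenerate draws are
counted separately, not imputed).

## Variant dynamics

MAF = alt/(ref+alt); undefined (NaN) at zero coverage, never imputed as 0.

*Consensus filter.* WES mode eliminates variants identified by a single
caller, with total coverage < 30 in **all** samples, alternate coverage < 5
in **all** samples, germline VAF ≥ 1 %, population-database membership, or
silent/intergenic/intronic annotation; the drop log counts every rule a
variant violates. Targeted mode keeps variants called by ≥ 2 callers and
sets per-sample detection status at ≥ 3 mutant reads; the barcoded-panel
mode additionally requires ≥ 100 total reads for a sample to count as
detected (low stromal-contamination coverage otherwise produces false
negatives). The filter is idempotent.

*ΔMAF.* Mean metastasis MAF minus mean primary MAF per variant, Welch
two-tailed t-test, classified enriched/depleted at |ΔMAF| ≥ 0.15 and
p ≤ 0.05 — unadjusted, mirroring the published significance rule, which
applies no multiple-testing correction here. Groups need ≥ 2 defined MAFs
each; otherwise the variant is marked untestable.

*De novo candidates* require zero WES alternate reads and < 7 deep-sequencing
alternate reads in every MFP sample (deep-sequenced samples below that
cutoff are treated as non-mutant), plus targeted detection (≥ 3 mutant
reads) in ≥ 1 metastasis of exactly one mouse — a true de novo event is
vanishingly unlikely to recur in independent animals.

*Repeat-artifact filter.* For each mutation pair, the 2×2 table of reads
spanning both loci (both / only A / only B / neither) is tested for
independence with the Pearson chi-square without continuity correction;
when any expected cell is below 5 the test falls back to Fisher's exact
test (the source method names only "a Chi-square test"; the fallback keeps
small-count p-values honest and is configurable by construction of the
input). Benjamini–Hochberg is applied across testable pairs; flagged means
q < 0.05; flagged pairs co-occurring in > 1 % of their spanning reads are
discarded, and both members of a discarded pair are removed. "1 % of the
reads" is read as 1 % of reads spanning the pair (the alternative — 1 % of
all sample reads — is not computable from a pair table). Pairs with an
all-zero margin are untestable and logged.

*qPCR human fraction*: 100·2^(−ΔCt,h) / (2^(−ΔCt,h) + 2^(−ΔCt,m)).

*Sample similarity*: Pearson correlation over the MAFs defined in both
samples of a pair; complete-linkage hierarchical clustering on Euclidean
distances over variants defined in every sample; sample columns are sorted
by id first so leaf order is deterministic.

## Cluster stability

Candidate clusters are each variant's modal post-burn-in label (ties to the
smallest label); default burn-in 2,500 iterations, matching the upstream
MCMC convention of 10,000 iterations with a quarter discarded. The
co-assignment matrix P[i,j] is the fraction of retained iterations with
equal labels. Within-cluster pair probabilities are binned as below
(p < 0.5), low (0.5 ≤ p < 0.9) and high (0.9 ≤ p ≤ 1); the published rule
defines only the two upper bins, and the explicit "below" bin makes the
chi-square partition total. The null ("random") distribution is likewise
unspecified; the default baseline is the category frequencies over *all*
unordered variant pairs in the trace, with a uniform-over-categories
alternative behind `baseline="uniform"`. Each cluster's observed counts are
compared to baseline expectations by chi-square goodness of fit; a category
with zero expected count is merged into below+low (logged); Bonferroni
correction multiplies raw p by the number of candidate clusters; robust
means adjusted p < 0.05. Singleton clusters are untestable and reported
non-robust with reason "too small".

## Synthetic-data generator

The generator emulates the study conditions: MOI 0.2 Poisson labeling (cells
with zero integrants are unlabeled and excluded; multi-integrant cells carry
one barcode pair per integrant and emit reads split evenly across their
pairs), engraftment Bernoulli(p_TIC = 0.04), negative-binomial MFP clone
sizes (mean 100, dispersion 1 — the pellet-distribution observation
motivates the NB; the mean and dispersion are desk-scale choices), lesion
seeders drawn without replacement with probability ∝ abundance^α (α = 1 by
default; no quantitative seeding model is published, so α is a free
parameter), and a per-mouse dominant set drawn from the low-abundance half
of engrafted clones and amplified 500-fold inside lesions, shared across
that mouse's lesions as observed for dominant metastatic barcodes. Dominant
clones are forced into every lesion's seeder set so dominant ⊆ seeding ⊆
engrafted holds by construction. Reads are multinomial over lesion
abundances; substitutions are iid per base at rate ε to one of the three
other bases; a junk fraction (default 5 %) of uniform random 40-mers models
off-target material. Per-sample emitted reads always equal the configured
depth. Defaults use 30,000 cells per mouse — scaled down from the hundreds
of thousands of labeled cells in the real experiments so a full simulated
mouse runs in seconds — which preserves the ~4 % bottleneck and the
dominance structure but not the absolute barcode counts of the real cohort;
tests therefore assert recovery of planted structure, not published counts.

Both read halves draw from the same half-library by default (whether the
two real half-libraries differ is not stated); a second library can be
supplied. The variant-table generator uses a heterozygous-diploid
convention: expected MAF = 0.5 × Σ_k genotype[v,k]·mixing[k,s], alternate
reads ~ Binomial(depth, MAF); copy-number effects on MAF are out of scope.
The trace generator flips each variant to a uniformly chosen *other*
cluster with a per-variant probability, which gives closed-form
co-assignment expectations ((1−f)² + f²/(K−1) within clusters) used as test
oracles.

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawns (one stream per mouse), so identical
(params, seed) give byte-identical outputs.

## Numerical and degenerate-input choices

- Half-library generation is rejection sampling with an attempt cap
  (2,000 × n); infeasible (n, length, min_dist) requests raise rather than
  loop.
- Dominance prefix uses a 1e−12 slack on the cumulative-share comparison so
  exact-boundary cases (e.g. uniform 100 barcodes at threshold 0.95 → 95)
  are not float-dependent.
- t-tests on two identical constant groups return (t = 0, p = 1) instead of
  NaN.
- Jaccard of two empty sets is 0 with a warning.
- The chi-square artifact test is skipped (logged untestable) for tables
  with an all-zero margin.
- Pipeline configs reject unknown keys recursively; exit codes are 0
  (success), 2 (config error), 3 (stage failure).

## Validation problem sizes

The test suite exercises: exact noiseless round-trips on a 12-barcode
library; dominant/seeding recovery on a simulated mouse with 300-seeder
lesions at 100,000 reads per sample; ΔMAF classification over 100 simulated
phantoms (3 primaries vs 6 metastases, depth 1,500, subclone mixing
0.10 → 0.70); artifact-filter false-positive control on 10,000 independent
pairs at 1,000 spanning reads; CI coverage over 1,000 simulated assays at
f = 0.1; and cluster-stability recall/false-acceptance over 200 traces of
1,000 iterations (flip rates 0.05 vs 0.45). These sizes were chosen so the
whole suite runs in well under a minute of simulation time per check while
keeping Monte-Carlo error small relative to the asserted margins.

## Known limitations

- The quantifier is exact only relative to its stated tolerance model; it
  does not model indels, quality scores or UMIs.
- The single-hit model assumes independent cell action; multi-hit or
  heterogeneity extensions are out of scope, and the liver discrepancy
  above is inherited from the published table, not resolved here.
- The generator does not simulate copy-number segments, RNA expression,
  spatial structure, or cross-metastasis reseeding; passing tests show the
  pipeline recovers planted structure under the stated noise model, not
  that it is robust to artifacts absent from that model (PCR jackpotting,
  index hopping, chimeric reads).
- The stability test's null baseline is an interpretation (see above);
  both baselines are exposed, and conclusions should be checked under each
  when clusters are borderline.
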