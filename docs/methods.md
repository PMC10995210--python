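# Methods

This note documents the models, defaults and design choices behind
`ssnflight`, and what the synthetic cohorts do and do not show about
real data.

## Pipeline model

**Normalization.** The count matrix is filtered (genes with zero counts
in strictly more than `zero_fraction_threshold` = 0.20 of samples are
dropped, boundary equality retained) and transformed to
`log2(count / size_factor + 1)`. Size factors are median-of-ratios: per
sample, the median over all-positive genes of count divided by the
gene's geometric mean across samples; if no gene is everywhere positive
the library-size ratio is used with a logged warning. This transform
keeps the two properties correlation analysis relies on — log2 scale and
library-size normalization. It is intentionally simpler than a
regularized-log fit with gene-wise shrinkage; Pearson correlation
downstream is insensitive to the shrinkage detail at the cohort sizes
used here, and the transform is pluggable for users who prefer another.

**Per-sample networks.** LIONESS linear interpolation over leave-one-out
Pearson correlations. Conventions: a pair involving a zero-variance gene
scores 0 (no evidence, keeps the interpolation total); the threshold
`w = μ(D) + 2σ(D)` uses the sample standard deviation (ddof = 1) of the
absolute scores and a strict `>`; by default D ranges over all gene
pairs (`pair_scope = all_pairs`), with `ppi_pairs` available when the
gene universe makes all-pairs scoring impractical. The background is the
full cohort by default; `ssn_background = tissue|dataset` restricts the
background to the sample's stratum (experimental). A per-stratum
background recovers stratum-private co-expression that a pooled
background dilutes — the tissue-stratified tests use it for exactly that
reason.

**Degrees, distances, embedding.** Degree vectors over the union of SSN
node sets (0 where absent; column sums equal twice the edge count).
Jaccard distance on edge sets, with two empty networks defined as
identical (distance 0, logged). Metric MDS via SMACOF with 4 restarts,
300-iteration cap, tolerance 1e-6 equivalent (`eps` 1e-9), seeded.

**DIG testing.** Per gene, Levene's test (scipy default, median-centred)
on the GC and SF degree vectors; Levene p < 0.05 selects Welch's t-test,
otherwise the pooled-variance t-test — the only reading under which the
variance-homogeneity step is consequential. Two-sided p; DIG means
p < alpha (default 0.05, uncorrected; a Benjamini–Hochberg flag exists
and is off by default). Zero variance in both groups is degenerate:
p = 1 when the means agree, else p = 0, counted in the log. Stratified
comparisons pair the SF samples of a stratum with GC samples sharing a
dataset accession.

**Dose grouping.** Spaceflight samples only. All C(U−1, 2) three-way
contiguous partitions of the U unique doses are scored by
KNeighborsClassifier (k = 5, Euclidean on degree vectors) under seeded
stratified 5-fold cross-validation; pooled out-of-fold predictions give
macro F1 and one-vs-rest AUC from neighbor-vote fractions. Partitions
with any class smaller than the fold count are infeasible and skipped.
Ties in F1 break toward more balanced group sizes, then lower low-cut.
k, the F1 averaging and the CV scheme are configurable because the
method fixes none of them.

**Differential network.** Edge occurrence counts per condition; the DIN
keeps edges with |n_GC − n_SF| strictly greater than the threshold. The
reference threshold 20 is calibrated to a 290-vs-301-sample cohort; the
default "auto" mode rescales it proportionally to the mean group size
(minimum 1), e.g. 2 for a 30/30 cohort. Hubs are the top-10 by weighted
degree (sum of incident DIN weights), ties broken lexicographically so
the cut is deterministic; ego networks take the top-30 most co-occurring
partners per condition with all count-ties at the cutoff included.

**Enrichment.** Ranking by `FC = (mean d_SF + ε) / (mean d_GC + ε)` with
ε = 0.5 so zero-degree genes stay rankable (ε → 0 recovers the plain
ratio where defined). GSEA is the weighted Kolmogorov–Smirnov running
sum (hit increments ∝ |score|^1 normalized over set hits, miss decrement
1/(n − n_hits)), ES the signed extremum, and an add-one two-sided
permutation p-value under gene-label permutation (default 1000
permutations, seeded). Disease degrees count distinct input genes per
disease after score ≥ 0.3 and evidence-index ≥ 0 filters.

## Synthetic cohorts

The generator draws a latent gene × sample Gaussian matrix with a
target correlation structure per (tissue, condition, dose-regime) cell,
maps it through per-gene log2 means (uniform in `mean_log2_range`) and a
log2 SD of 1.0, exponentiates and rounds to integer counts. Correlation
targets that are infeasible as written (e.g. high-correlation stars) are
projected to the nearest positive-semidefinite correlation matrix;
uniform blocks are used wherever exact realization matters.

Two planted-signal mechanisms exist:

* **Correlation blocks** (`perturbed_pairs`): gene pairs whose SF
  correlation is `rho_base + scale · (rho_sf − rho_base)`, with the
  scale set per dose regime and optional regime (`min_regime`) and
  tissue gating.
* **Dispersion markers** (`regime_variance_markers`): genes whose latent
  log-scale SD is multiplied by `variance_inflation` in SF samples of
  their regime (nested or exclusive keying). Inflated genes light up
  more of their PPI edges through the influence tail of the per-sample
  estimator, giving a consistent per-sample degree elevation.

The second mechanism exists because of a quantitative property of the
estimator worth stating plainly: a per-sample edge call requires
`|e_ij(s)| > μ + 2σ` over a pair universe whose null scores are
heavy-tailed products of z-scores, so a single pair's per-sample
presence tops out near ~15% even as its planted correlation approaches
1, and co-occurring edge calls within a correlation block are strongly
correlated (whole blocks light up in a few influential samples). Mean
degree differences from correlation planting are therefore small and
bursty, and only become reliably detectable at cohort sizes of a few
hundred samples per condition. Dispersion inflation, by contrast,
produces low-noise per-sample signatures and is the vehicle for the
dose-regime and hub structures.

Preset study conditions (all seeded, all deterministic):

* `default_cohort_spec` — 300 genes, 30 GC + 30 SF in 6 paired
  datasets, one SF-only correlated block of 30 genes (rho 0.95, regime
  scales 0.9/0.95/1.0), two baseline modules (rho 0.5), 5 silenced
  genes, published dose intervals 4.66–7.14 / 7.592–8.295 /
  8.49–22.099 mGy. The DIG power analysis runs this preset at the
  study's group sizes (290 GC / 301 SF), where p-value ranking separates
  the 30 planted genes with AUROC ≈ 0.92–0.99 depending on the cohort
  draw; at 30/30 the same effect is not reliably detectable — an honest
  property of the method, not of the implementation.
* `null_cohort_spec` — 1000 genes, 40 + 40 samples, no planted pairs;
  used with a dense PPI (extra-edge fraction 0.2) so degree vectors are
  non-degenerate. Measured type-I rate at alpha 0.05: ≈ 0.04–0.06.
* `dose_recovery_spec` — 40 GC + 120 SF (30/40/50 per regime, the
  published intervals), exclusive dispersion tiers of 40/60/80 genes
  wired as four-gene PPI cliques, inflation 3.0. The exhaustive KNN
  search recovers the exact planted boundaries with macro F1 ≈ 1.0.
* `hub_recovery_spec` — ten hub genes, each dispersion-inflated
  (3.5×) with ten inflated PPI spokes and weak hub–spoke SF correlation;
  no baseline modules (inflation raises SF thresholds, which would turn
  ordinary module edges into spurious GC-differential edges). Eight to
  ten of the ten hubs land in the top-10 weighted-degree list across
  seeds.
* `two_tissue_spec` — two tissues with strong tissue-private modules;
  SSNs cluster by tissue in the MDS embedding (2-means agreement ≥ 0.9).

The synthetic PPI contains every planted pair plus a fraction
(default 0.01) of random extra pairs; marker cliques are wired in
explicitly because co-inflation is only visible to the pipeline where a
pair is a PPI edge.

## What the synthetic results do and do not show

The generator emulates the statistical structure the pipeline assumes —
condition-specific correlation, dose-scaled perturbation strength,
tissue blocks, paired batches — but not sequencing error, library-size
variation, batch effects beyond dataset labels, or realistic
co-expression topology. Passing tests therefore demonstrate that the
implementation computes the method correctly and that the method can
recover planted structure under favorable, known conditions; they do not
certify biological findings on real cohorts, where effect sizes,
confounding and annotation error are far less forgiving.

## Numerical and reproducibility choices

All randomness flows from one root seed (config `seed`), fanned out per
stage through independent seed-sequence children (kept below 2^31).
Outputs are TSV with rounded floats and canonical orderings, so reruns
are byte-identical. Ties are always broken deterministically
(lexicographic gene ids; balanced-then-low-cut for dose partitions).
Analysis problem sizes in the test-suite and acceptance script (group
sizes of a few hundred at most, 300–1000 genes) were chosen so the full
pipeline and its calibration checks complete in minutes on one CPU while
staying in the regime where each statistical claim is measurable.

## Known limitations

* The per-sample estimator's edge calls are influence-tail events; degree
  signals from pure correlation rewiring need hundreds of samples per
  condition, and the detection-power spread across cohort draws is wide
  (AUROC ≈ 0.83–0.99 at 290/301 over arbitrary seeds).
* Exhaustive partition search is quadratic in the number of unique doses
  and runs one CV per partition (~100 s for ~5,700 partitions at 120
  samples).
* The empty-vs-empty network distance convention (0) makes degenerate
  cohorts look maximally similar; such events are logged.
* Homolog mapping keeps the first occurrence order and drops unmapped
  genes silently except for a logged count.
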