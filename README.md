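# ssnflight

Single-sample network analysis of spaceflight transcriptomes.

Bulk RNA-seq cohorts from spaceflight experiments pool many missions,
tissues and platforms, which makes direct expression comparisons fragile.
This package implements an analysis that side-steps that heterogeneity by
converting each sample's expression profile into a *gene interaction
network* and comparing networks instead of expression values. It is aimed
at computational biologists studying how spaceflight (microgravity plus
space radiation) rewires gene-interaction patterns in mouse tissues, and
at anyone who wants a fully testable, download-free reimplementation of
the single-sample-network (SSN) methodology.

## The method

1. **Preprocessing.** Genes with zero counts in more than 20% of samples
   are removed; counts are normalized with median-of-ratios size factors
   and moved to log2 scale.
2. **Single-sample networks (LIONESS).** With N samples, the network of
   sample *s* is the linear interpolation

   `e_ij(s) = N · (e_ij(N) − e_ij(N−s)) + e_ij(N−s)`

   where `e_ij(N)` is the Pearson correlation of genes *i, j* over all
   samples and `e_ij(N−s)` the correlation with *s* removed. Per sample,
   the absolute scores form a distribution *D*; edges with
   `|e_ij(s)| > w = μ(D) + 2σ(D)` are kept and intersected with a
   protein–protein interaction (PPI) network.
3. **Node features.** Each gene gets a degree vector
   `d = (d_1, …, d_n)` across all SSNs (0 where absent). Networks are
   compared by Jaccard distance on edge sets
   (`dist = 1 − |E1∩E2| / |E1∪E2|`) and embedded in 2-D with metric MDS.
4. **Differentially interacted genes (DIGs).** Per gene, Levene's test
   gates a two-sided two-sample t-test (Welch if variances differ) on the
   ground-control (GC) vs spaceflight (SF) degree vectors; p < 0.05 marks
   a DIG.
5. **Dose grouping.** All three-way contiguous partitions of the sorted
   absorbed radiation doses (mGy) are enumerated; each candidate grouping
   is scored by a K-nearest-neighbors classifier on degree vectors under
   stratified five-fold cross-validation, and the partition with the best
   macro F1 wins.
6. **Differential network and hubs.** Each edge's occurrence count is
   tallied per condition; edges with `|n_GC − n_SF|` above a threshold
   form the differentially interacted network (DIN), with weight
   `|n_GC − n_SF|`. A gene's weighted degree is the sum of its incident
   DIN weights; the top 10 are hub genes, each with tie-inclusive top-30
   ego networks per condition.
7. **Enrichment and diseases.** Genes are ranked by degree fold change
   `FC_i = mean(d_i^SF) / mean(d_i^GC)` and tested against gene sets with
   a weighted Kolmogorov–Smirnov enrichment score and gene-label
   permutation p-values; DIGs map to human homologs and score diseases by
   their degree in a filtered gene–disease association network.

Because the original cohorts require repository-scale downloads, the
package ships a synthetic cohort generator (`ssnflight.synthetic_data`)
that plants known correlation blocks, dispersion markers, dose regimes,
tissue structure and paired GC/SF batches, so every stage is testable
end-to-end against known ground truth.

## Worked example

```bash
# write a synthetic cohort (counts, metadata, PPI, gene sets, truth)
ssnflight simulate --seed 1

# run every stage; outputs land in results/
ssnflight run-all --seed 1
```

The run prints one summary line per stage:

```
preprocess  {'n_genes_raw': 300, 'n_genes_filtered': 295, 'n_samples': 60}
ssn         {'n_ssns': 60, 'n_ppi_edges': 1079, 'total_edges': 3330, 'pair_scope': 'all_pairs'}
features    {'n_degree_genes': 285, 'mds_stress': 271.572989}
dosegroup   {'n_partitions_scored': 136, 'best_f1_macro': 0.46592, ...}
digstats    {'n_digs_global': 18, 'n_rows': 1995}
diffnet     {'din_threshold': 2, 'n_din_edges': 172, 'hubs': ['G0003', ...]}
enrich      {'n_gene_sets_tested': 6, 'n_human_digs': 18, 'n_diseases': 5}
```

Reading it: the 300-gene, 60-sample cohort keeps 295 genes after the
zero-fraction filter; one SSN is built per sample (3,330 edges in total
after thresholding and PPI intersection); 18 genes differ significantly
in degree between spaceflight and ground control at this small cohort
size; 172 edges exceed the differential-count threshold and define the
DIN whose top-10 weighted-degree genes are reported as hubs. The
`results/` directory holds the full tables (degree matrix, DIG
statistics per stratum, dose-partition leaderboard, DIN edges, ego
networks, GSEA results, disease degrees) plus a `manifest.json` snapshot
of the configuration and per-stage counts. Reruns with the same seed are
byte-identical.

Every stage is also callable as a library function — see
`ssnflight.ssn.build_all_ssns`, `ssnflight.digstats.identify_digs`,
`ssnflight.dosegroup.search_best_partition`,
`ssnflight.diffnet.hub_genes`, `ssnflight.enrich.gsea`.

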