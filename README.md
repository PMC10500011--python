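# snfomics

Integrative multi-omic subtyping of tumor cohorts by similarity network
fusion (SNF), with the downstream analyses a discovery study needs:
signature-based group extension, cross-cohort subclass validation,
matched transcript–protein (posttranscriptional) statistics, gene-set
enrichment and cell-type deconvolution, and clinical association tests.
It is written for computational biologists analysing small multi-omic
cohorts — e.g. pediatric low-grade gliomas profiled on the transcriptome
and proteome — where no single layer separates molecular groups cleanly
but their fusion does.

A first-class synthetic cohort generator reproduces the statistical
structure such a study assumes (two latent groups, planted markers, weak
mRNA–protein coupling, opposite group-wise protein/mRNA ratio shift,
uninformative methylation, cell-type mixing, clinical covariates) with
full ground truth, so every pipeline stage is testable end to end.

## The model

Per omic layer *v*, samples *i, j* at Euclidean distance *d(i,j)* over
z-scored features get the scaled exponential kernel

    W(i,j) = exp( −d(i,j)² / (μ · ε(i,j)) ),
    ε(i,j) = [ mean_K(i) + mean_K(j) + d(i,j) ] / 3,

with `mean_K(i)` the mean distance of *i* to its K nearest neighbours
(defaults K = 10, μ = 0.5). Two row-stochastic operators drive the
fusion: the full kernel **P** (off-diagonal mass ½, diagonal ½) and the
sparse K-NN kernel **S**. Cross-network diffusion iterates, for T = 10
rounds,

    P⁽ᵛ⁾ ← S⁽ᵛ⁾ · mean_{w≠v}( P⁽ʷ⁾ ) · S⁽ᵛ⁾ᵀ,

re-normalised each round; the fused network is the average of the final
status matrices. Groups come from normalised spectral clustering of the
fused network, with the cluster number chosen by the Laplacian eigengap.
Downstream: Welch-t differential features (p ≤ 0.05, |FC| ≥ 2) ranked by
p; top-50 up/down signatures; Pearson-dissimilarity average-linkage
extension; submap (bidirectional marker enrichment with permutation FDR);
per-pair Pearson coupling and median log protein/mRNA ratios per group;
preranked GSEA on t statistics; NNLS deconvolution; Kaplan–Meier /
log-rank, χ² / Fisher, and Mann–Whitney clinical tests.

## Worked example

```python
import snfomics as sf
from sklearn.metrics import adjusted_rand_score

cohort = sf.simulate_cohort(sf.CohortConfig(), seed=1)   # 28 samples, 2 groups
(mrna, protein), _ = sf.align_cohort([cohort.mrna, cohort.protein])

params = sf.SNFParams(K=10, mu=0.5, T=10)
fusion = sf.fuse_networks([sf.build_affinity(m, params) for m in (mrna, protein)], params)
best_k, gaps = sf.estimate_num_clusters(fusion.fused)
labels = sf.spectral_cluster(fusion.fused, k=best_k, seed=0)
print(best_k, adjusted_rand_score(cohort.true_labels.reindex(mrna.sample_ids), labels))

pairs = sf.match_pairs(mrna, protein)
_, median_r = sf.pair_correlations(pairs)
print(round(median_r, 3))
```

prints

```
2 1.0
0.166
```

meaning: the eigengap selects two clusters, the fused clustering matches
the planted groups exactly (adjusted Rand index 1.0), and the median
Pearson correlation over the 2000 matched transcript–protein pairs is
0.166 — the weak global coupling the generator is calibrated to. The
scripts in `examples/` walk through each capability (simulation, fusion,
signatures + submap, posttranscriptional ratios, enrichment +
deconvolution, clinical statistics) and print annotated numbers.

A thin CLI mirrors the library: `snfomics simulate|preprocess|fuse|
signatures|extend|submap|ratio|gsea|score|deconvolve|clinical|run`, where
`run` executes the whole discovery workflow and writes a JSON manifest
(inputs, parameters, seed, per-stage wall time).

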