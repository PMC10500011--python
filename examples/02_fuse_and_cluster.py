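"""Similarity network fusion and spectral clustering of a two-layer cohort.

Builds one patient-similarity graph per layer (scaled exponential
Euclidean kernel, K=10 neighbours, mu=0.5), fuses them by T=10 rounds of
cross-network diffusion, picks the number of clusters by the eigengap of
the fused graph's normalised Laplacian, and compares the clustering with
the planted truth.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import snfomics as sf

cohort = sf.simulate_cohort(sf.CohortConfig(), seed=1)
(mrna, protein), _ = sf.align_cohort([cohort.mrna, cohort.protein])

params = sf.SNFParams(K=10, mu=0.5, T=10)
affinities = [sf.build_affinity(layer, params) for layer in (mrna, protein)]
fusion = sf.fuse_networks(affinities, params)

best_k, gaps = sf.estimate_num_clusters(fusion.fused)
labels = sf.spectral_cluster(fusion.fused, k=best_k, seed=0)
ari = adjusted_rand_score(cohort.true_labels.reindex(mrna.sample_ids), labels)
edges = sf.export_network(fusion.fused, mrna.sample_ids)

print(f"eigengaps for k=2..6:     {np.round(gaps, 4)}")
print(f"selected cluster number:  {best_k} (largest gap => strongest split)")
print(f"ARI vs planted groups:    {ari:.2f} (1.0 = perfect recovery)")
print(f"covering edge list:       {len(edges)} edges, every sample connected")
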