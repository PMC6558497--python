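"""Cluster the cells and identify each cluster's cell type by marker score.

The score of marker set G_t in cluster i sums, over every other cluster j,
the log2 fold changes of the markers significant in the i-vs-j negative-
binomial test: C_i(G_t) = sum_j C_ij(G_t). Each cluster gets the type with
the maximal score.
"""

from sctme import (
    SyntheticSpec, generate_dataset, run_qc, normalize_log,
    pca_embed_cluster, cluster_type_scores,
)

matrix, truth = generate_dataset(SyntheticSpec(seed=0))
matrix, _ = run_qc(matrix)
normalize_log(matrix)

clustering = pca_embed_cluster(matrix, embedding="pca", seed=0)
print(f"{clustering.n_clusters} clusters from "
      f"{len(clustering.variable_genes)} variable genes, 30 PCs")

scores = cluster_type_scores(matrix, clustering, truth.markers)
print("\ncluster x type score matrix (C_i(G_t)):")
print(scores.scores.round(1).to_string())
print("\nassignment:", dict(scores.assignment))
# each planted population should win its own marker column by a wide margin
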