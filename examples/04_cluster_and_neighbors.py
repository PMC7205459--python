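"""Fingerprint clustering and correlation-neighbor ranking.

Genes acting in one pathway respond to the same conditions, so their
fitness fingerprints correlate. Here three planted 5-gene groups are
recovered as contiguous blocks of the dendrogram, and the top correlation
neighbors of a group member are its pathway partners — the logic that links
an uncharacterised gene to the characterised genes it behaves like.
"""

from tnprof import cluster_profiles, correlation_neighbors, simulate_pathway_profiles

matrix, labels = simulate_pathway_profiles(
    n_groups=3, genes_per_group=5, n_conditions=10, noise_sd=0.03, seed=5
)
result = cluster_profiles(matrix, metric="euclidean", method="complete")
print("dendrogram leaf order:")
print("  " + " ".join(result.leaf_order))

query = "group2_gene1"
ranking = correlation_neighbors(matrix, query)
print(f"\ntop 5 correlation neighbors of {query}:")
for rec in ranking.neighbors.head(5).itertuples(index=False):
    print(f"  {rec.gene_id:15s} r = {rec.r:.3f}  ({labels[rec.gene_id]})")
print("\nneighbors with r near 1 share the query's pathway; background genes trail.")
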