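"""Log2 occupancy-ratio matrix around the TSS, clustered by k-means.

Builds mutant and wild-type occupancy from noisy fragments, forms the
per-gene log2 mutant/control ratio over ±750 bp, groups genes into 5
clusters, and saves a heatmap (blue = occupancy gain in the mutant, red =
loss). With the symmetric simulator all genes share the same true response
— a gain inside the shrinking NDR — so clusters differ only by noise level.
"""

from ndrscape import (
    AnalysisParams,
    SimParams,
    compute_occupancy,
    kmeans_cluster,
    normalize_track,
    ratio_matrix,
    sample_fragments,
    sample_genome,
    save_heatmap,
)

params = SimParams(n_genes=100, mutant_shrink=40, depth=50, seed=3)
sizes, tss, truth = sample_genome(params)
tracks = {
    cond: normalize_track(compute_occupancy(sample_fragments(truth, cond, params), sizes))
    for cond in ("wt", "mutant")
}

analysis = AnalysisParams(flank=750, pseudocount=1.0, k=5, seed=3)
matrix = ratio_matrix(tracks["mutant"], tracks["wt"], tss, analysis)
clusters = kmeans_cluster(matrix, analysis)
save_heatmap(matrix, clusters, "heatmap.png")

print(f"matrix: {len(matrix.gene_ids)} genes x {matrix.values.shape[1]} positions")
print(f"excluded (window out of bounds): {len(matrix.excluded)}")
for label in range(1, clusters.k + 1):
    n = sum(1 for v in clusters.labels.values() if v == label)
    print(f"cluster {label}: {n} genes, upstream mean ratio "
          f"{clusters.upstream_means[label]:+.3f}")
# Cluster 1 always has the strongest mean occupancy gain over [-500, 0] —
# the labels are renumbered canonically so they are comparable across runs.
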