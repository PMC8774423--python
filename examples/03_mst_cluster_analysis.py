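"""MST construction and inconsistent-edge cutting on nucleus centroids.

Builds the Euclidean MST over ground-truth centroids, removes edges longer
than three cluster radii, and summarizes intra- and inter-cluster distances.
"""

from nucleiclust import build_mst, cut_edges, inter_cluster_summary, intra_cluster_summary
from nucleiclust.synthdata import PatchSpec, generate_patch

spec = PatchSpec(seed=7)
_, _, centroids = generate_patch(spec)

mst = build_mst(centroids[["row", "col"]].to_numpy())
print(f"{mst.n_vertices} vertices, {len(mst.edges)} MST edges, "
      f"total weight {mst.total_weight:.1f} px")

threshold = 3 * spec.cluster_spread
clusters = cut_edges(mst, "threshold", threshold)
print(f"cutting edges > {threshold:.0f} px removes {len(clusters.cut_edges)} edges "
      f"-> {clusters.n_clusters} clusters (generator planted {spec.n_clusters})")

first = intra_cluster_summary(clusters.member_coordinates(0))
print(f"cluster 0: {len(clusters.clusters[0])} nuclei, intra-MST total "
      f"{first.mst_total:.1f} px, hull area {first.hull_area:.0f} px^2")

inter = inter_cluster_summary(clusters)
print(f"inter-cluster MST total {inter.mst_total:.1f} px, "
      f"centroid-to-centroid average {inter.c2c_avg:.1f} px")
print("-> these per-cluster and cross-cluster summaries feed the 26-feature")
print("   descriptor used for grading.")
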