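"""The 26-feature cluster descriptor of one patch."""

from nucleiclust import build_mst, cut_edges, extract_features
from nucleiclust.synthdata import PatchSpec, generate_patch

spec = PatchSpec(seed=7)
_, _, centroids = generate_patch(spec)
clusters = cut_edges(
    build_mst(centroids[["row", "col"]].to_numpy()), "threshold", 3 * spec.cluster_spread
)
vector = extract_features(clusters)

print(vector.to_series().round(2).to_string())
print()
print("-> one row of the feature table per patch; distances in px, areas in")
print("   px^2. 'total' features sum per-cluster values, 'average' features")
print("   divide by the number of clusters.")
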