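"""The fixed 26-feature cluster descriptor.

One feature vector summarizes the cluster structure of a whole patch. The
features come in four families:

* 13 intra-cluster distance features — per-cluster nucleus-to-nucleus
  pairwise distances and intra-cluster MST edge weights, aggregated over
  clusters ("total X" = sum of per-cluster X, "average X" = mean of
  per-cluster X);
* 4 cluster-area features (convex-hull area of member centroids):
  average, total, minimum and maximum;
* 8 inter-cluster features — centroid-to-centroid distances between cluster
  means (total/average/min/max) and the inter-cluster MST over cluster means
  (total/average/min/max); all 0 when there is a single cluster;
* the number of clusters.

Units are pixels for distances, squared pixels for areas, and a count for the
number of clusters. The order of :func:`feature_names` is fixed and is the
column order of every feature table this package writes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mstcluster import ClusterError, ClusterSet, inter_cluster_summary, intra_cluster_summary

#: Canonical, ordered names of the 26 features.
FEATURE_NAMES: tuple[str, ...] = (
    "total intra-cluster total MST distance",
    "total intra-cluster nucleus to nucleus maximum distance",
    "inter-cluster centroid to centroid total distance",
    "inter-cluster total MST distance",
    "number of clusters",
    "total intra-cluster maximum MST distance",
    "average intra-cluster nucleus to nucleus minimum distance",
    "average intra-cluster nucleus to nucleus maximum distance",
    "average intra-cluster maximum MST distance",
    "average cluster area",
    "total intra-cluster nucleus to nucleus total distance",
    "total intra-cluster minimum MST distance",
    "total intra-cluster nucleus to nucleus minimum distance",
    "inter-cluster maximum MST distance",
    "average intra-cluster total MST distance",
    "average intra-cluster minimum MST distance",
    "total cluster area",
    "inter-cluster average MST distance",
    "average intra-cluster nucleus to nucleus average distance",
    "inter-cluster centroid to centroid average distance",
    "minimum area of a cluster",
    "average intra-cluster nucleus to nucleus total distance",
    "inter-cluster centroid to centroid minimum distance",
    "inter-cluster centroid to centroid maximum distance",
    "maximum area of a cluster",
    "inter-cluster minimum MST distance",
)


def feature_names() -> list[str]:
    """The 26 feature names in their canonical, stable order."""
    return list(FEATURE_NAMES)


def snake_names() -> list[str]:
    """Machine-friendly lower_snake_case aliases, same order."""
    return [n.replace("-", " ").replace(" ", "_").lower() for n in FEATURE_NAMES]


@dataclass
class FeatureVector:
    """The 26 named scalars of one patch, in canonical order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(26)

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=feature_names())


def extract_features(cluster_set: ClusterSet) -> FeatureVector:
    """Compute the 26-feature descriptor of a :class:`ClusterSet`.

    Per-cluster statistics come from :func:`intra_cluster_summary`; the
    cross-cluster statistics from :func:`inter_cluster_summary`. Raises
    :class:`ClusterError` on an empty cluster set.
    """
    if cluster_set.n_clusters == 0:
        raise ClusterError("cannot extract features from an empty cluster set")
    intra = [
        intra_cluster_summary(cluster_set.member_coordinates(i), members)
        for i, members in enumerate(cluster_set.clusters)
    ]
    inter = inter_cluster_summary(cluster_set)

    def tot(attr: str) -> float:
        return float(sum(getattr(s, attr) for s in intra))

    def avg(attr: str) -> float:
        return float(np.mean([getattr(s, attr) for s in intra]))

    areas = [s.hull_area for s in intra]
    values = {
        "total intra-cluster total MST distance": tot("mst_total"),
        "total intra-cluster nucleus to nucleus maximum distance": tot("pairwise_max"),
        "inter-cluster centroid to centroid total distance": inter.c2c_total,
        "inter-cluster total MST distance": inter.mst_total,
        "number of clusters": float(cluster_set.n_clusters),
        "total intra-cluster maximum MST distance": tot("mst_max"),
        "average intra-cluster nucleus to nucleus minimum distance": avg("pairwise_min"),
        "average intra-cluster nucleus to nucleus maximum distance": avg("pairwise_max"),
        "average intra-cluster maximum MST distance": avg("mst_max"),
        "average cluster area": avg("hull_area"),
        "total intra-cluster nucleus to nucleus total distance": tot("pairwise_total"),
        "total intra-cluster minimum MST distance": tot("mst_min"),
        "total intra-cluster nucleus to nucleus minimum distance": tot("pairwise_min"),
        "inter-cluster maximum MST distance": inter.mst_max,
        "average intra-cluster total MST distance": avg("mst_total"),
        "average intra-cluster minimum MST distance": avg("mst_min"),
        "total cluster area": tot("hull_area"),
        "inter-cluster average MST distance": inter.mst_avg,
        "average intra-cluster nucleus to nucleus average distance": avg("pairwise_avg"),
        "inter-cluster centroid to centroid average distance": inter.c2c_avg,
        "minimum area of a cluster": float(min(areas)),
        "average intra-cluster nucleus to nucleus total distance": avg("pairwise_total"),
        "inter-cluster centroid to centroid minimum distance": inter.c2c_min,
        "inter-cluster centroid to centroid maximum distance": inter.c2c_max,
        "maximum area of a cluster": float(max(areas)),
        "inter-cluster minimum MST distance": inter.mst_min,
    }
    return FeatureVector(np.array([values[name] for name in FEATURE_NAMES]))
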