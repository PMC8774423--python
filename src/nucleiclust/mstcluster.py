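"""Minimum-spanning-tree cluster analysis of nucleus centroids.

Nucleus centroids are the vertices of a complete Euclidean graph; a minimum
spanning tree is grown with Prim's algorithm, and clusters are obtained
Zahn-style by deleting inconsistent edges — either every edge longer than a
pixel threshold (default 10 px) or the k longest edges. Removing k edges from
a tree leaves exactly k+1 connected components.

Per-cluster summaries cover the two distance families used downstream:
nucleus-to-nucleus (all unordered pairwise distances within a cluster, plus
the intra-cluster MST over its members) and centroid-to-centroid (distances
between cluster means, plus the inter-cluster MST over cluster means).
Cluster area is the convex hull of member centroids.

Ties between equal-weight edges are broken by lowest vertex index so that the
tree edge set — not just its total weight, which is always unique — is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform


class ClusterError(ValueError):
    pass


def euclidean_distance(p1, p2) -> float:
    """Euclidean distance between two 2-D points."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return float(np.sqrt(np.sum((p1 - p2) ** 2)))


@dataclass
class MSTGraph:
    """An MST over centroid vertices: (i, j, weight) edges, i < j."""

    vertices: np.ndarray
    edges: list[tuple[int, int, float]]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))


@dataclass
class ClusterStats:
    """Distance/area summary of one cluster of nuclei.

    Pairwise stats are over all unordered member pairs; MST stats are over
    the intra-cluster MST edges. A singleton cluster has every value 0.
    ``hull_area`` is the convex-hull area of member centroids (0 for fewer
    than 3 non-collinear members).
    """

    members: list[int]
    centroid: np.ndarray
    pairwise_min: float = 0.0
    pairwise_max: float = 0.0
    pairwise_total: float = 0.0
    pairwise_avg: float = 0.0
    mst_min: float = 0.0
    mst_max: float = 0.0
    mst_total: float = 0.0
    mst_avg: float = 0.0
    hull_area: float = 0.0
    mst_edges: list[tuple[int, int, float]] = field(default_factory=list)


@dataclass
class InterClusterStats:
    """Centroid-to-centroid and inter-MST summaries across clusters.

    All values are 0 when there is a single cluster.
    """

    centroids: np.ndarray
    c2c_min: float = 0.0
    c2c_max: float = 0.0
    c2c_total: float = 0.0
    c2c_avg: float = 0.0
    mst_min: float = 0.0
    mst_max: float = 0.0
    mst_total: float = 0.0
    mst_avg: float = 0.0
    mst_edges: list[tuple[int, int, float]] = field(default_factory=list)


@dataclass
class ClusterSet:
    """Partition of MST vertices into clusters after edge cutting."""

    vertices: np.ndarray
    clusters: list[list[int]]
    cut_edges: list[tuple[int, int, float]]
    retained_edges: list[tuple[int, int, float]]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def member_coordinates(self, cluster_index: int) -> np.ndarray:
        return self.vertices[self.clusters[cluster_index]]


def build_mst(centroids) -> MSTGraph:
    """Grow a minimum spanning tree over centroids with Prim's algorithm.

    Works on the complete Euclidean graph; equal-weight frontier edges are
    resolved toward the smallest vertex index. Duplicate points are allowed
    (zero-weight edges). 0 or 1 points give an edgeless graph.
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n <= 1:
        return MSTGraph(vertices=pts, edges=[])

    dist = squareform(pdist(pts))
    in_tree = np.zeros(n, dtype=bool)
    best_weight = np.full(n, np.inf)
    best_parent = np.full(n, -1, dtype=int)

    in_tree[0] = True
    best_weight[:] = dist[0]
    best_parent[:] = 0
    edges: list[tuple[int, int, float]] = []

    for _ in range(n - 1):
        # argmin over vertices outside the tree; np.argmin takes the first
        # (lowest-index) minimizer, which is the deterministic tie-break
        masked = np.where(in_tree, np.inf, best_weight)
        u = int(np.argmin(masked))
        p = int(best_parent[u])
        edges.append((min(p, u), max(p, u), float(dist[p, u])))
        in_tree[u] = True
        better = (~in_tree) & (dist[u] < best_weight)
        best_weight[better] = dist[u][better]
        best_parent[better] = u
    return MSTGraph(vertices=pts, edges=edges)


def cut_edges(mst: MSTGraph, mode: str = "threshold", value: float = 10.0) -> ClusterSet:
    """Delete inconsistent MST edges and return the resulting clusters.

    mode="threshold": remove every edge with weight > value (pixels).
    mode="top_k": remove the int(value) largest-weight edges, ties resolved
    by (i, j) vertex-index order; k >= number of edges leaves all singletons.

    Clusters are the connected components of the remaining forest, each
    listed as sorted vertex indices, ordered by their smallest member.
    """
    if mode not in ("threshold", "top_k"):
        raise ClusterError(f"unknown cut mode: {mode!r}")
    edges = list(mst.edges)
    if mode == "threshold":
        removed = [e for e in edges if e[2] > value]
        retained = [e for e in edges if e[2] <= value]
    else:
        k = int(value)
        ranked = sorted(edges, key=lambda e: (-e[2], e[0], e[1]))
        removed = ranked[:k]
        removed_set = set((i, j) for i, j, _ in removed)
        retained = [e for e in edges if (e[0], e[1]) not in removed_set]

    n = mst.n_vertices
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, _ in retained:
        parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for v in range(n):
        groups.setdefault(find(v), []).append(v)
    clusters = sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
    return ClusterSet(
        vertices=mst.vertices,
        clusters=clusters,
        cut_edges=removed,
        retained_edges=retained,
    )


def intra_cluster_summary(member_coordinates, members: list[int] | None = None) -> ClusterStats:
    """Pairwise, intra-MST and hull-area summary of one cluster.

    A singleton cluster yields all-zero statistics; an empty cluster is an
    error. Hull area is 0 for collinear or < 3 member sets.
    """
    pts = np.asarray(member_coordinates, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ClusterError("empty cluster")
    members = list(range(len(pts))) if members is None else list(members)
    stats = ClusterStats(members=members, centroid=pts.mean(axis=0))
    if len(pts) >= 2:
        d = pdist(pts)
        stats.pairwise_min = float(d.min())
        stats.pairwise_max = float(d.max())
        stats.pairwise_total = float(d.sum())
        stats.pairwise_avg = float(d.mean())
        tree = build_mst(pts)
        weights = [w for _, _, w in tree.edges]
        stats.mst_min = float(min(weights))
        stats.mst_max = float(max(weights))
        stats.mst_total = float(sum(weights))
        stats.mst_avg = float(np.mean(weights))
        stats.mst_edges = tree.edges
    stats.hull_area = _hull_area(pts)
    return stats


def inter_cluster_summary(cluster_set: ClusterSet) -> InterClusterStats:
    """Centroid-to-centroid distances and inter-cluster MST summary.

    Cluster centroids are the means of member coordinates; with a single
    cluster every inter value is 0. An empty cluster set is an error.
    """
    if cluster_set.n_clusters == 0:
        raise ClusterError("empty cluster set")
    centroids = np.stack(
        [cluster_set.member_coordinates(i).mean(axis=0) for i in range(cluster_set.n_clusters)]
    )
    stats = InterClusterStats(centroids=centroids)
    if len(centroids) >= 2:
        d = pdist(centroids)
        stats.c2c_min = float(d.min())
        stats.c2c_max = float(d.max())
        stats.c2c_total = float(d.sum())
        stats.c2c_avg = float(d.mean())
        tree = build_mst(centroids)
        weights = [w for _, _, w in tree.edges]
        stats.mst_min = float(min(weights))
        stats.mst_max = float(max(weights))
        stats.mst_total = float(sum(weights))
        stats.mst_avg = float(np.mean(weights))
        stats.mst_edges = tree.edges
    return stats


def _hull_area(pts: np.ndarray) -> float:
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # .volume is area in 2-D
    except QhullError:
        return 0.0  # collinear members span no area
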