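"""Independent brute-force oracles used only by the tests.

Everything here deliberately avoids the code paths it checks: spanning trees
are enumerated exhaustively, the 26-feature vector is recomputed with plain
Python loops plus scipy's own MST routine, the convex hull comes from
shapely, and Otsu's threshold is maximized by scanning all 256 candidates.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree as _scipy_mst
from shapely.geometry import MultiPoint


def exhaustive_mst_weight(points: np.ndarray) -> float:
    """Minimum spanning tree total weight by enumerating all trees (n <= 7)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n <= 1:
        return 0.0
    all_edges = [
        (i, j, math.dist(pts[i], pts[j])) for i in range(n) for j in range(i + 1, n)
    ]
    best = math.inf
    for subset in itertools.combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for i, j, _ in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(w for _, _, w in subset))
    return best


def scipy_mst_weight(points: np.ndarray) -> float:
    """MST total weight via scipy's csgraph routine (independent of Prim)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) <= 1:
        return 0.0
    dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return float(_scipy_mst(dist).sum())


def hull_area_shapely(points: np.ndarray) -> float:
    return float(MultiPoint([tuple(p) for p in np.asarray(points)]).convex_hull.area)


def brute_force_features(clusters: list[np.ndarray]) -> dict[str, float]:
    """The 26 features recomputed from member coordinate lists, from scratch."""

    def pairwise(pts):
        return [math.dist(pts[i], pts[j]) for i in range(len(pts)) for j in range(i + 1, len(pts))]

    def mst_weights(pts):
        # assumes distinct points (zero-weight edges would vanish from the
        # sparse tree); random_cluster_geometry never produces duplicates
        pts = np.asarray(pts, dtype=float)
        if len(pts) <= 1:
            return []
        dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        return [w for w in _scipy_mst(dist).toarray().ravel() if w > 0]

    per = []
    for pts in clusters:
        pts = np.asarray(pts, dtype=float)
        pw = pairwise(pts)
        mw = mst_weights(pts)
        per.append(
            {
                "pw_min": min(pw) if pw else 0.0,
                "pw_max": max(pw) if pw else 0.0,
                "pw_tot": sum(pw) if pw else 0.0,
                "pw_avg": sum(pw) / len(pw) if pw else 0.0,
                "mst_min": min(mw) if mw else 0.0,
                "mst_max": max(mw) if mw else 0.0,
                "mst_tot": sum(mw) if mw else 0.0,
                "area": hull_area_shapely(pts) if len(pts) >= 3 else 0.0,
                "centroid": pts.mean(axis=0),
            }
        )
    k = len(per)
    cents = np.array([p["centroid"] for p in per])
    c2c = pairwise(cents) if k >= 2 else []
    imw = mst_weights(cents) if k >= 2 else []

    def tot(key):
        return sum(p[key] for p in per)

    def avg(key):
        return tot(key) / k

    return {
        "total intra-cluster total MST distance": tot("mst_tot"),
        "total intra-cluster nucleus to nucleus maximum distance": tot("pw_max"),
        "inter-cluster centroid to centroid total distance": sum(c2c) if c2c else 0.0,
        "inter-cluster total MST distance": sum(imw) if imw else 0.0,
        "number of clusters": float(k),
        "total intra-cluster maximum MST distance": tot("mst_max"),
        "average intra-cluster nucleus to nucleus minimum distance": avg("pw_min"),
        "average intra-cluster nucleus to nucleus maximum distance": avg("pw_max"),
        "average intra-cluster maximum MST distance": avg("mst_max"),
        "average cluster area": avg("area"),
        "total intra-cluster nucleus to nucleus total distance": tot("pw_tot"),
        "total intra-cluster minimum MST distance": tot("mst_min"),
        "total intra-cluster nucleus to nucleus minimum distance": tot("pw_min"),
        "inter-cluster maximum MST distance": max(imw) if imw else 0.0,
        "average intra-cluster total MST distance": avg("mst_tot"),
        "average intra-cluster minimum MST distance": avg("mst_min"),
        "total cluster area": tot("area"),
        "inter-cluster average MST distance": sum(imw) / len(imw) if imw else 0.0,
        "average intra-cluster nucleus to nucleus average distance": avg("pw_avg"),
        "inter-cluster centroid to centroid average distance": sum(c2c) / len(c2c) if c2c else 0.0,
        "minimum area of a cluster": min(p["area"] for p in per),
        "average intra-cluster nucleus to nucleus total distance": avg("pw_tot"),
        "inter-cluster centroid to centroid minimum distance": min(c2c) if c2c else 0.0,
        "inter-cluster centroid to centroid maximum distance": max(c2c) if c2c else 0.0,
        "maximum area of a cluster": max(p["area"] for p in per),
        "inter-cluster minimum MST distance": min(imw) if imw else 0.0,
    }


def brute_force_otsu(image: np.ndarray) -> int:
    """Threshold maximizing between-class variance, scanning all 256 levels."""
    hist = np.bincount(np.asarray(image, dtype=np.uint8).ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_var = 0, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (np.arange(t + 1) * hist[: t + 1]).sum() / w0
        mu1 = (np.arange(t + 1, 256) * hist[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def random_cluster_geometry(rng: np.random.Generator, max_clusters: int = 5) -> list[np.ndarray]:
    """Random well-formed cluster member lists for oracle comparisons."""
    k = int(rng.integers(1, max_clusters + 1))
    clusters = []
    for _ in range(k):
        center = rng.uniform(0, 400, 2)
        n = int(rng.integers(1, 9))
        clusters.append(center + rng.normal(0, 12, (n, 2)))
    return clusters
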