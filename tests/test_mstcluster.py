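"""MST construction, inconsistent-edge cutting, and cluster summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleiclust.mstcluster import (
    ClusterError,
    build_mst,
    cut_edges,
    euclidean_distance,
    inter_cluster_summary,
    intra_cluster_summary,
)

from .oracles import exhaustive_mst_weight, hull_area_shapely, scipy_mst_weight


class TestEuclideanDistance:
    def test_identity_and_pythagoras(self):
        assert euclidean_distance((0, 0), (0, 0)) == 0
        assert euclidean_distance((0, 0), (3, 4)) == 5

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0, 100, (2, 2))
            assert euclidean_distance(a, b) == euclidean_distance(b, a)


class TestBuildMST:
    def test_degenerate_sizes(self):
        assert build_mst(np.empty((0, 2))).edges == []
        assert build_mst([(5, 5)]).edges == []

    def test_collinear_triple_brute_force(self):
        tree = build_mst([(0, 0), (3, 0), (7, 0)])
        assert sorted((i, j, w) for i, j, w in tree.edges) == [(0, 1, 3.0), (1, 2, 4.0)]
        assert tree.total_weight == 7.0

    def test_unit_square_total_weight(self):
        tree = build_mst([(0, 0), (0, 1), (1, 0), (1, 1)])
        assert tree.total_weight == pytest.approx(3.0)

    def test_edge_count_is_vertices_minus_one(self, rng):
        for n in [1, 2, 5, 30]:
            tree = build_mst(rng.uniform(0, 100, (n, 2)))
            assert len(tree.edges) == max(n - 1, 0)

    def test_optimality_against_exhaustive_enumeration(self, rng):
        for _ in range(40):
            pts = rng.uniform(0, 50, (int(rng.integers(2, 8)), 2))
            assert build_mst(pts).total_weight == pytest.approx(
                exhaustive_mst_weight(pts), rel=1e-12
            )

    def test_agrees_with_scipy_on_larger_sets(self, rng):
        pts = rng.uniform(0, 300, (80, 2))
        assert build_mst(pts).total_weight == pytest.approx(scipy_mst_weight(pts), rel=1e-9)

    def test_duplicate_points_allowed(self):
        tree = build_mst([(1, 1), (1, 1), (4, 5)])
        assert len(tree.edges) == 2
        assert min(w for _, _, w in tree.edges) == 0.0


class TestCutEdges:
    def test_removing_k_edges_yields_k_plus_1_components(self, rng):
        pts = rng.uniform(0, 200, (40, 2))
        tree = build_mst(pts)
        for k in [0, 3, 9, 25, 39]:
            cs = cut_edges(tree, "top_k", k)
            assert cs.n_clusters == k + 1

    def test_top_k_exceeding_edges_gives_all_singletons(self):
        tree = build_mst([(0, 0), (1, 0), (2, 0)])
        cs = cut_edges(tree, "top_k", 10)
        assert cs.n_clusters == 3 and all(len(c) == 1 for c in cs.clusters)

    def test_threshold_extremes(self, rng):
        pts = rng.uniform(0, 100, (15, 2))
        tree = build_mst(pts)
        weights = [w for _, _, w in tree.edges]
        assert cut_edges(tree, "threshold", max(weights)).n_clusters == 1
        assert cut_edges(tree, "threshold", min(weights) - 1e-9).n_clusters == 15

    def test_retained_edges_respect_threshold(self, rng):
        pts = rng.uniform(0, 300, (60, 2))
        cs = cut_edges(build_mst(pts), "threshold", 40.0)
        assert all(w <= 40.0 for _, _, w in cs.retained_edges)
        assert all(w > 40.0 for _, _, w in cs.cut_edges)

    def test_clusters_partition_vertices(self, rng):
        pts = rng.uniform(0, 100, (25, 2))
        cs = cut_edges(build_mst(pts), "threshold", 20.0)
        flat = sorted(v for c in cs.clusters for v in c)
        assert flat == list(range(25))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ClusterError):
            cut_edges(build_mst([(0, 0), (1, 1)]), "magic", 1)


class TestIntraSummary:
    def test_singleton_is_all_zero(self):
        s = intra_cluster_summary([(5, 5)])
        assert s.pairwise_total == s.mst_total == s.hull_area == 0.0

    def test_collinear_triple_hand_enumerated(self):
        s = intra_cluster_summary([(0, 0), (3, 0), (7, 0)])
        assert (s.pairwise_min, s.pairwise_max, s.pairwise_total) == (3, 7, 14)
        assert s.pairwise_avg == pytest.approx(14 / 3)
        assert (s.mst_min, s.mst_max, s.mst_total) == (3, 4, 7)
        assert s.hull_area == 0.0  # collinear spans no area

    def test_unit_square_hull_area(self):
        s = intra_cluster_summary([(0, 0), (0, 1), (1, 0), (1, 1)])
        assert s.hull_area == pytest.approx(1.0)

    def test_hull_area_matches_shapely(self, rng):
        pts = rng.uniform(0, 50, (12, 2))
        s = intra_cluster_summary(pts)
        assert s.hull_area == pytest.approx(hull_area_shapely(pts), rel=1e-9)

    def test_mst_total_bounded_by_pairwise_total(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 60, (int(rng.integers(2, 10)), 2))
            s = intra_cluster_summary(pts)
            assert s.mst_total <= s.pairwise_total + 1e-9

    def test_empty_cluster_is_error(self):
        with pytest.raises(ClusterError):
            intra_cluster_summary(np.empty((0, 2)))


class TestInterSummary:
    def _cluster_set(self, groups):
        pts = np.vstack(groups)
        tree = build_mst(pts)
        cs = cut_edges(tree, "threshold", np.inf)
        # overwrite partition with the intended grouping
        cs.clusters = []
        start = 0
        for g in groups:
            cs.clusters.append(list(range(start, start + len(g))))
            start += len(g)
        return cs

    def test_two_cluster_centroid_distance(self):
        cs = self._cluster_set([np.array([[-1, 0], [1, 0]]), np.array([[5, 8], [7, 8]])])
        s = inter_cluster_summary(cs)
        assert s.c2c_min == pytest.approx(10.0)  # means (0,0) and (6,8)

    def test_single_cluster_all_zero(self):
        cs = self._cluster_set([np.array([[0, 0], [1, 1]])])
        s = inter_cluster_summary(cs)
        assert s.c2c_total == s.mst_total == 0.0

    def test_three_centroids_brute_force(self):
        groups = [np.array([[0.0, 0.0]]), np.array([[10.0, 0.0]]), np.array([[0.0, 10.0]])]
        s = inter_cluster_summary(self._cluster_set(groups))
        assert s.c2c_total == pytest.approx(20 + np.sqrt(200))
        assert s.mst_total == pytest.approx(20.0)
        assert s.mst_min == s.mst_max == pytest.approx(10.0)


@settings(deadline=None, max_examples=25)
@given(
    scale=st.floats(0.1, 50.0),
    seed=st.integers(0, 10_000),
)
def test_distances_scale_linearly_and_areas_quadratically(scale, seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 100, (10, 2))
    base = intra_cluster_summary(pts)
    scaled = intra_cluster_summary(pts * scale)
    assert scaled.pairwise_total == pytest.approx(base.pairwise_total * scale, rel=1e-9)
    assert scaled.mst_total == pytest.approx(base.mst_total * scale, rel=1e-9)
    assert scaled.hull_area == pytest.approx(base.hull_area * scale**2, rel=1e-9)
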