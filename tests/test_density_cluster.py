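import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepstager.density_cluster import (
    ClusteringError,
    ClusterParams,
    DegenerateDimensionError,
    PeakSaddleMismatchError,
    allocate_remaining,
    bandwidths,
    chunk_indices,
    cluster_subset,
    delaunay_graph,
    density_order,
    detect_cores,
    estimate_density,
    scan_level_ranks,
)

from conftest import make_blob_scores


class TestChunkIndices:
    def test_86400_epochs_split_into_16_interleaved_subsets(self):
        subsets = chunk_indices(86_400, 5400)
        assert len(subsets) == 16
        assert all(len(s) == 5400 for s in subsets)
        assert np.array_equal(
            np.sort(np.concatenate(subsets)), np.arange(86_400)
        )
        np.testing.assert_array_equal(subsets[0][:3], [0, 16, 32])

    def test_small_dataset_is_one_subset(self):
        subsets = chunk_indices(5000, 5400)
        assert len(subsets) == 1
        assert np.array_equal(subsets[0], np.arange(5000))

    def test_interleave_enumeration(self):
        # m=10, max=4 -> k=3 subsets {0,3,6,9}, {1,4,7}, {2,5,8}
        subsets = chunk_indices(10, 4)
        assert [s.tolist() for s in subsets] == [[0, 3, 6, 9], [1, 4, 7], [2, 5, 8]]

    @given(m=st.integers(1, 3000), max_subset=st.integers(1, 500))
    @settings(max_examples=60, deadline=None)
    def test_subsets_partition_index_set(self, m, max_subset):
        subsets = chunk_indices(m, max_subset)
        flat = np.concatenate(subsets)
        assert len(flat) == m
        assert np.array_equal(np.sort(flat), np.arange(m))
        assert max(len(s) for s in subsets) <= max(max_subset, 1)


class TestBandwidths:
    def test_single_point_rejected(self):
        with pytest.raises(ClusteringError):
            bandwidths(np.zeros((1, 3)), 1.0)

    def test_normal_reference_value(self):
        rng = np.random.default_rng(0)
        h = bandwidths(rng.normal(size=(1000, 4)), h_mult=1.0)
        # (4 / ((d+2) n))^(1/(d+4)) = (4/6000)^(1/8) ~ 0.40 for unit sd
        np.testing.assert_allclose(h, 0.40, atol=0.05)

    def test_linear_in_h_mult(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 3))
        np.testing.assert_allclose(bandwidths(x, 1.4), 2 * bandwidths(x, 0.7))

    def test_zero_spread_dimension_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(50, 3))
        x[:, 1] = 7.0
        with pytest.raises(DegenerateDimensionError):
            bandwidths(x)


class TestEstimateDensity:
    def test_symmetric_points_have_equal_density(self):
        x = np.array([[1.0, 0.0], [-1.0, 0.0]])
        d = estimate_density(x, np.array([0.5, 0.5]))
        assert d[0] == pytest.approx(d[1])
        assert np.all(d > 0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(200, 2))
        bw = bandwidths(x, 0.7)
        fast = estimate_density(x, bw)
        slow = np.zeros(200)
        norm = 1.0 / (200 * bw.prod() * 2 * np.pi)
        for i in range(200):
            for j in range(200):
                z = ((x[i] - x[j]) / bw) ** 2
                slow[i] += np.exp(-0.5 * z.sum())
        slow *= norm
        np.testing.assert_allclose(fast, slow, rtol=1e-10)

    def test_centroid_denser_than_outlier(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(500, 2))
        x[0] = x[1:].mean(axis=0)
        x[1] = x[0] + 5.0  # ~5 sigma away in each dim
        bw = bandwidths(x, 0.7)
        d = estimate_density(x, bw)
        assert d[0] > d[1]

    def test_integrates_to_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(150, 2))
        bw = bandwidths(x, 1.0)
        lo, hi = x.min(axis=0) - 5 * bw, x.max(axis=0) + 5 * bw
        mc = np.random.default_rng(6).uniform(lo, hi, size=(40_000, 2))
        # evaluate the same product-kernel estimate at the MC points
        vals = np.zeros(len(mc))
        norm = 1.0 / (len(x) * bw.prod() * 2 * np.pi)
        for xi in x:
            z = ((mc - xi) / bw) ** 2
            vals += np.exp(-0.5 * z.sum(axis=1))
        vals *= norm
        integral = vals.mean() * np.prod(hi - lo)
        assert integral == pytest.approx(1.0, rel=0.05)


class TestDelaunayGraph:
    def test_triangle(self):
        g = delaunay_graph(np.array([[0.0, 0], [1, 0], [0, 1]]))
        assert len(g.edges) == 3

    def test_single_simplex_complete_graph(self):
        pts = np.vstack([np.zeros(3), np.eye(3)])  # 4 affinely independent in 3-D
        g = delaunay_graph(pts)
        assert len(g.edges) == 6  # C(4,2)

    def test_edges_have_empty_circumcircle_witness(self):
        # every Delaunay edge must belong to a triangle whose circumcircle
        # holds no other point (checked by brute force)
        rng = np.random.default_rng(7)
        pts = rng.uniform(size=(50, 2))
        g = delaunay_graph(pts)

        def circumcircle(a, b, c):
            ax, ay = a
            bx, by = b
            cx, cy = c
            d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
            ux = (
                (ax**2 + ay**2) * (by - cy)
                + (bx**2 + by**2) * (cy - ay)
                + (cx**2 + cy**2) * (ay - by)
            ) / d
            uy = (
                (ax**2 + ay**2) * (cx - bx)
                + (bx**2 + by**2) * (ax - cx)
                + (cx**2 + cy**2) * (bx - ax)
            ) / d
            center = np.array([ux, uy])
            return center, np.linalg.norm(a - center)

        for a, b in g.edges:
            found = False
            for c in range(50):
                if c in (a, b):
                    continue
                try:
                    center, r = circumcircle(pts[a], pts[b], pts[c])
                except ZeroDivisionError:
                    continue
                dists = np.linalg.norm(pts - center, axis=1)
                inside = dists < r - 1e-9
                inside[[a, b, c]] = False
                if not inside.any():
                    found = True
                    break
            assert found, f"edge ({a},{b}) has no empty-circumcircle triangle"

    def test_too_few_points_rejected(self):
        with pytest.raises(ClusteringError):
            delaunay_graph(np.zeros((2, 2)))


class TestScanLevels:
    def test_stride_10_visits_every_tenth_point(self):
        stride, ranks = scan_level_ranks(5400, 540)
        assert stride == 10
        assert ranks == list(range(9, 5400, 10))
        assert ranks[-1] == 5399

    def test_minimum_density_point_always_included(self):
        stride, ranks = scan_level_ranks(103, 10)
        assert ranks[-1] == 102

    def test_full_resolution(self):
        stride, ranks = scan_level_ranks(50, 50)
        assert stride == 1
        assert ranks == list(range(50))


class TestDetectCores:
    def test_two_separated_blobs_recover_generating_labels(self, two_blobs_2d):
        pts, truth = two_blobs_2d
        bw = bandwidths(pts, 0.7)
        dens = estimate_density(pts, bw)
        graph = delaunay_graph(pts)
        core, n_clusters, diag = detect_cores(dens, graph, n_grid=len(pts))
        assert n_clusters == 2
        is_core = core > 0
        # map cluster ids to generating blobs by majority
        agree = 0
        for cid in (1, 2):
            members = truth[core == cid]
            agree += max((members == 1).sum(), (members == 2).sum())
        assert agree / is_core.sum() >= 0.99

    def test_single_blob_is_one_cluster(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(200, 2))
        res = cluster_subset(pts, ClusterParams(h_mult=0.7, n_grid=200, max_subset=200))
        assert res.n_clusters == 1

    @pytest.mark.parametrize("h_mult", [0.1, 0.2])
    def test_undersmoothed_density_raises_mismatch(self, blob_scores_4d, h_mult):
        with pytest.raises(PeakSaddleMismatchError):
            cluster_subset(blob_scores_4d, ClusterParams(h_mult=h_mult))

    def test_same_fixture_completes_at_default_smoothing(self, blob_scores_4d):
        res = cluster_subset(blob_scores_4d, ClusterParams(h_mult=0.7))
        assert res.n_clusters >= 3

    def test_level_components_match_networkx_oracle(self):
        rng = np.random.default_rng(8)
        pts = np.vstack(
            [rng.normal(0, 1, (150, 2)), rng.normal((6, 0), 1, (150, 2))]
        )
        bw = bandwidths(pts, 0.7)
        dens = estimate_density(pts, bw)
        graph = delaunay_graph(pts)
        core, ncl, diag = detect_cores(
            dens, graph, n_grid=30, record_levels=True
        )
        order = density_order(dens)
        G = nx.Graph()
        G.add_nodes_from(range(len(pts)))
        G.add_edges_from(graph.edges.tolist())
        for rank, parts in zip(diag.level_ranks, diag.level_partitions):
            above = set(order[: rank + 1].tolist())
            expected = {
                frozenset(c) for c in nx.connected_components(G.subgraph(above))
            }
            assert set(parts) == expected

    def test_labels_invariant_to_density_rescaling(self, two_blobs_2d):
        pts, _ = two_blobs_2d
        bw = bandwidths(pts, 0.7)
        dens = estimate_density(pts, bw)
        graph = delaunay_graph(pts)
        a = detect_cores(dens, graph, n_grid=len(pts))
        b = detect_cores(dens * 37.5, graph, n_grid=len(pts))
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_cluster_count_nonincreasing_in_h_mult(self, blob_scores_4d):
        counts = []
        for h in (0.7, 1.0, 1.5, 2.5):
            res = cluster_subset(
                blob_scores_4d,
                ClusterParams(h_mult=h, n_grid=len(blob_scores_4d),
                              max_subset=len(blob_scores_4d)),
            )
            counts.append(res.n_clusters)
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] >= 1


class TestAllocateRemaining:
    def _instance(self):
        pts, truth = (
            np.vstack(
                [
                    np.random.default_rng(0).normal(0, 1, (200, 2)),
                    np.random.default_rng(1).normal((10, 10), 1, (200, 2)),
                ]
            ),
            np.repeat([1, 2], 200),
        )
        bw = bandwidths(pts, 0.7)
        dens = estimate_density(pts, bw)
        graph = delaunay_graph(pts)
        return pts, truth, dens, graph

    def test_identity_when_all_labeled(self):
        pts, truth, dens, graph = self._instance()
        labels = allocate_remaining(truth.copy(), dens, graph, pts)
        np.testing.assert_array_equal(labels, truth)

    def test_single_unlabeled_point_takes_neighbor_cluster(self):
        pts, truth, dens, graph = self._instance()
        partial = truth.copy()
        partial[5] = 0
        labels = allocate_remaining(partial, dens, graph, pts)
        assert labels[5] == truth[5]

    def test_two_blob_allocation_matches_generator(self, two_blobs_2d):
        pts, truth = two_blobs_2d
        bw = bandwidths(pts, 0.7)
        dens = estimate_density(pts, bw)
        graph = delaunay_graph(pts)
        core, ncl, _ = detect_cores(dens, graph, n_grid=len(pts))
        labels = allocate_remaining(core, dens, graph, pts)
        assert np.all(labels > 0)
        agree = 0
        for cid in (1, 2):
            members = truth[labels == cid]
            agree += max((members == 1).sum(), (members == 2).sum())
        assert agree / len(pts) >= 0.98

    def test_no_cores_is_error(self):
        pts, truth, dens, graph = self._instance()
        with pytest.raises(ClusteringError):
            allocate_remaining(np.zeros(len(pts), dtype=int), dens, graph, pts)


class TestClusterSubset:
    def test_deterministic_rerun(self, two_blobs_2d):
        pts, _ = two_blobs_2d
        params = ClusterParams(h_mult=0.7, n_grid=400, max_subset=400)
        a = cluster_subset(pts, params)
        b = cluster_subset(pts, params)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.density, b.density)
        np.testing.assert_array_equal(a.is_core, b.is_core)

    def test_single_point_rejected(self):
        with pytest.raises(ClusteringError):
            cluster_subset(np.zeros((1, 2)), ClusterParams())

    def test_n_grid_scaled_for_small_subsets(self, two_blobs_2d):
        pts, _ = two_blobs_2d  # 400 points < max_subset 5400
        res = cluster_subset(pts, ClusterParams(h_mult=0.7))
        # 400 * 540 / 5400 = 40 levels -> stride 10
        assert res.diagnostics.stride == 10
        assert len(res.diagnostics.level_ranks) == 40  # every 10th of 400

    def test_every_point_labeled_within_1_to_n_clusters(self, blob_scores_4d):
        res = cluster_subset(blob_scores_4d, ClusterParams(h_mult=0.7))
        assert res.labels.min() >= 1
        assert res.labels.max() == res.n_clusters
        assert set(np.unique(res.labels)) == set(range(1, res.n_clusters + 1))
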