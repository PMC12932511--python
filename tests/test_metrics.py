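"""Nodal graph metrics against brute-force oracles, plus feature tables."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_adjacency
from eztopo.connectivity import BinaryNetwork
from eztopo.metrics import (FEATURE_COLUMNS, betweenness_centrality,
                            clustering_coefficient, local_efficiency,
                            nodal_feature_table, node_degree,
                            subnetwork_densities)

# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation's igraph/csgraph
# backends: plain BFS distances and path-count dynamic programming).


def bfs_distances(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(a[u]):
                    if dist[s, v] == np.inf:
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def oracle_degree(a):
    return np.array([sum(a[i]) for i in range(len(a))])


def oracle_clustering(a):
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = nbrs.size
        if k < 2:
            continue
        e = sum(a[u, v] for ii, u in enumerate(nbrs) for v in nbrs[ii + 1:])
        out[i] = 2 * e / (k * (k - 1))
    return out


def oracle_betweenness(a):
    n = a.shape[0]
    dist = bfs_distances(a)
    # sigma[s, t]: number of shortest s-t paths, by path-length DP
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1)
    order = np.argsort(dist, axis=None)
    for flat in order:
        s, t = divmod(flat, n)
        if s == t or not np.isfinite(dist[s, t]):
            continue
        preds = [u for u in np.flatnonzero(a[:, t])
                 if dist[s, u] == dist[s, t] - 1]
        sigma[s, t] = sum(sigma[s, u] for u in preds)
    bc = np.zeros(n)
    for i in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if s == i or t == i or not np.isfinite(dist[s, t]):
                    continue
                if dist[s, i] + dist[i, t] == dist[s, t]:
                    bc[i] += sigma[s, i] * sigma[i, t] / sigma[s, t]
    return bc


def oracle_local_efficiency(a):
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = nbrs.size
        if k < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        d = bfs_distances(sub)
        acc = 0.0
        for u in range(k):
            for v in range(k):
                if u != v and np.isfinite(d[u, v]):
                    acc += 1.0 / d[u, v]
        out[i] = acc / (k * (k - 1))
    return out


# ---------------------------------------------------------------------------


def path_graph(n):
    a = np.zeros((n, n), dtype=np.uint8)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a


class TestExamples:
    def test_complete_graph_degrees(self):
        a = np.ones((4, 4), dtype=np.uint8) - np.eye(4, dtype=np.uint8)
        assert np.array_equal(node_degree(a), [3, 3, 3, 3])
        assert np.allclose(clustering_coefficient(a), 1.0)
        assert np.allclose(local_efficiency(a), 1.0)  # neighbor triangle

    def test_path_degrees_and_betweenness(self):
        a = path_graph(3)
        assert np.array_equal(node_degree(a), [1, 2, 1])
        assert np.allclose(betweenness_centrality(a), [0.0, 1.0, 0.0])

    def test_triangle_and_star(self):
        tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.uint8)
        assert np.allclose(clustering_coefficient(tri), 1.0)
        star = np.zeros((4, 4), dtype=np.uint8)
        star[0, 1:] = star[1:, 0] = 1
        assert clustering_coefficient(star)[0] == 0.0
        assert local_efficiency(star)[0] == 0.0  # leaves mutually disconnected

    def test_four_cycle_betweenness(self):
        # each node lies on 1 of the 2 shortest paths of the opposite pair
        a = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]],
                     dtype=np.uint8)
        assert np.allclose(betweenness_centrality(a), 0.5)

    def test_normalized_betweenness_flag(self):
        a = path_graph(4)
        raw = betweenness_centrality(a)
        norm = betweenness_centrality(a, normalized=True)
        assert np.allclose(norm, raw / 3.0)  # (N-1)(N-2)/2 = 3

    def test_isolated_node_all_zero(self):
        a = np.zeros((3, 3), dtype=np.uint8)
        a[0, 1] = a[1, 0] = 1
        assert node_degree(a)[2] == 0
        assert clustering_coefficient(a)[2] == 0
        assert local_efficiency(a)[2] == 0
        assert betweenness_centrality(a)[2] == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("n,reps", [(6, 15), (9, 10), (12, 10)])
    def test_random_graphs_match_bruteforce(self, rng, n, reps):
        for _ in range(reps):
            a = random_adjacency(rng, n, p=float(rng.uniform(0.15, 0.6)))
            assert np.array_equal(node_degree(a), oracle_degree(a))
            assert np.allclose(clustering_coefficient(a), oracle_clustering(a),
                               atol=1e-12)
            assert np.allclose(betweenness_centrality(a), oracle_betweenness(a),
                               atol=1e-9)
            assert np.allclose(local_efficiency(a), oracle_local_efficiency(a),
                               atol=1e-12)

    def test_networkx_cross_check(self, rng):
        import networkx as nx

        for _ in range(5):
            a = random_adjacency(rng, 10, p=0.3)
            g = nx.from_numpy_array(a)
            nx_bc = np.array([v for _, v in sorted(
                nx.betweenness_centrality(g, normalized=False).items())])
            assert np.allclose(betweenness_centrality(a), nx_bc, atol=1e-9)
            nx_c = np.array([v for _, v in sorted(nx.clustering(g).items())])
            assert np.allclose(clustering_coefficient(a), nx_c, atol=1e-12)


class TestIdentities:
    def test_degree_sum_is_twice_edges(self, rng):
        a = random_adjacency(rng, 15, 0.3)
        assert node_degree(a).sum() == a.sum()

    def test_density_partition_identity(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 14))
            a = random_adjacency(rng, n, float(rng.uniform(0.2, 0.7)))
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False)] = True
            if (~mask).sum() < 2:
                continue
            rep = subnetwork_densities(a, mask)
            assert rep.e_ez + rep.e_nez + rep.e_cross == a.sum() // 2
            # direct edge-counting oracle
            idx_ez = np.flatnonzero(mask)
            e_ez = sum(a[u, v] for i, u in enumerate(idx_ez) for v in idx_ez[i + 1:])
            assert rep.e_ez == e_ez
            assert rep.d_ez == pytest.approx(
                e_ez / (len(idx_ez) * (len(idx_ez) - 1) / 2))


class TestDensities:
    def test_three_node_block(self):
        a = np.zeros((6, 6), dtype=np.uint8)
        ez = np.array([True, True, True, False, False, False])
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1  # 2 internal EZ edges
        rep = subnetwork_densities(a, ez)
        assert rep.d_ez == pytest.approx(2 / 3)
        assert rep.d_cross == 0.0

    def test_complete_graph_all_one(self):
        n = 7
        a = np.ones((n, n), dtype=np.uint8) - np.eye(n, dtype=np.uint8)
        ez = np.array([True, True, False, False, False, True, False])
        rep = subnetwork_densities(a, ez)
        assert rep.d_ez == rep.d_nez == rep.d_cross == 1.0

    def test_small_block_undefined_not_zero(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        ez = np.array([True, False, False, False])
        rep = subnetwork_densities(a, ez)
        assert np.isnan(rep.d_ez)
        assert rep.defined["d_ez"] is False
        assert rep.defined["d_cross"] is True


class TestFeatureTable:
    def _net(self, a, labels):
        return BinaryNetwork(a, 0.7, labels)

    def test_28_columns_for_seven_bands(self, rng):
        labels = [f"c{i}" for i in range(8)]
        nets = {b: self._net(random_adjacency(rng, 8, 0.4), labels)
                for b in ("full", "delta", "theta", "alpha", "beta", "gamma", "hf")}
        table = nodal_feature_table(nets)
        assert [c for c in table.columns if c != "node"] == list(FEATURE_COLUMNS)
        assert len(table) == 8

    def test_two_bands_give_eight_columns(self, rng):
        labels = [f"c{i}" for i in range(5)]
        nets = {b: self._net(random_adjacency(rng, 5, 0.5), labels)
                for b in ("full", "delta")}
        table = nodal_feature_table(nets)
        assert len([c for c in table.columns if c != "node"]) == 8

    def test_full_nd_column_is_definitional(self, rng):
        a = random_adjacency(rng, 6, 0.5)
        labels = [f"c{i}" for i in range(6)]
        table = nodal_feature_table({"full": self._net(a, labels)})
        assert np.array_equal(table["full_nd"].to_numpy(), node_degree(a))

    def test_inconsistent_nodes_rejected(self, rng):
        nets = {
            "full": self._net(random_adjacency(rng, 4, 0.5), list("abcd")),
            "delta": self._net(random_adjacency(rng, 4, 0.5), list("abce")),
        }
        with pytest.raises(ValueError):
            nodal_feature_table(nets)
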