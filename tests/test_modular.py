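"""Modularity Q, modular segregation index, and intra/inter edge counts."""

import numpy as np
import pytest

from thalmod.connectome import BinaryGraph, ConnMatrix, DEFAULT_LEVELS
from thalmod.modular import (
    inter_connections,
    intra_connections,
    modular_report,
    modular_segregation_index,
    modularity_q,
)
from thalmod.networks import N_NETWORKS, NETWORKS, default_partition


def graph_from_edges(n, edges, labels):
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(adj, sparsity=1.0, achieved_sparsity=1.0, node_partition=labels)


def brute_force_q(adj, labels):
    """Independent O(N^2) double-loop evaluation of the Newman sum."""
    two_e = adj.sum()
    k = adj.sum(axis=1)
    q = 0.0
    for i in range(adj.shape[0]):
        for j in range(adj.shape[0]):
            if labels[i] == labels[j]:
                q += adj[i, j] - k[i] * k[j] / two_e
    return q / two_e


class TestModularityQ:
    def test_single_module_gives_zero(self, rng):
        adj = (rng.random((8, 8)) < 0.4).astype(int)
        adj = np.triu(adj, 1)
        adj += adj.T
        g = BinaryGraph(adj, 1.0, 1.0)
        assert modularity_q(g, np.zeros(8, dtype=int)) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
        labels = np.array([0, 0, 0, 1, 1, 1])
        g = graph_from_edges(6, edges, labels)
        assert modularity_q(g, labels) == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 11))
            adj = np.triu((rng.random((n, n)) < 0.5).astype(float), 1)
            adj += adj.T
            if adj.sum() == 0:
                continue
            labels = rng.integers(0, 3, size=n)
            g = BinaryGraph(adj.astype(np.uint8), 1.0, 1.0)
            assert modularity_q(g, labels) == pytest.approx(
                brute_force_q(adj, labels), abs=1e-12
            )

    def test_matches_networkx(self, rng):
        import networkx as nx

        adj = np.triu((rng.random((10, 10)) < 0.5).astype(np.uint8), 1)
        adj += adj.T
        labels = rng.integers(0, 3, size=10)
        g = BinaryGraph(adj, 1.0, 1.0)
        communities = [set(np.flatnonzero(labels == m)) for m in np.unique(labels)]
        expected = nx.community.modularity(nx.from_numpy_array(adj), communities)
        assert modularity_q(g, labels) == pytest.approx(expected, abs=1e-12)

    def test_detected_partition_cross_check(self):
        # Louvain on two disjoint triangles finds them, matching the fixed-label Q
        from thalmod.modular import detected_partition_q

        edges = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
        labels = np.array([0, 0, 0, 1, 1, 1])
        g = graph_from_edges(6, edges, labels)
        q, communities = detected_partition_q(g, seed=0)
        assert q == pytest.approx(0.5)
        assert {frozenset(c) for c in communities} == {
            frozenset({0, 1, 2}), frozenset({3, 4, 5})
        }

    def test_edgeless_graph_rejected(self):
        g = BinaryGraph(np.zeros((4, 4), dtype=np.uint8), 1.0, 0.0)
        with pytest.raises(ValueError, match="edgeless"):
            modularity_q(g, np.zeros(4, dtype=int))


class TestMSI:
    def uniform_conn(self, within, between, n_in=3, n_out=3):
        labels = np.array([0] * n_in + [1] * n_out)
        vals = np.full((n_in + n_out, n_in + n_out), between)
        vals[:n_in, :n_in] = within
        vals[n_in:, n_in:] = within
        np.fill_diagonal(vals, 1.0)
        return ConnMatrix(vals), labels

    def test_uniform_toy_matrix(self):
        conn, labels = self.uniform_conn(0.6, 0.2)
        assert modular_segregation_index(conn, labels, 0) == pytest.approx((0.6 - 0.2) / 0.6)

    def test_no_segregation(self):
        conn, labels = self.uniform_conn(0.4, 0.4)
        assert modular_segregation_index(conn, labels, 0) == pytest.approx(0.0)

    def test_perfect_segregation(self):
        conn, labels = self.uniform_conn(0.5, 0.0)
        assert modular_segregation_index(conn, labels, 0) == pytest.approx(1.0)

    def test_negative_between_counts_as_zero(self):
        conn, labels = self.uniform_conn(0.5, -0.3)
        assert modular_segregation_index(conn, labels, 0) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        conn, labels = self.uniform_conn(0.0, 0.0)
        with pytest.raises(ValueError, match="no positive"):
            modular_segregation_index(conn, labels, 0)
        with pytest.raises(ValueError, match=">= 2 nodes"):
            modular_segregation_index(conn, np.array([0, 1, 1, 1, 1, 1]), 0)


class TestEdgeCounts:
    def test_complete_module(self):
        labels = np.array([0, 0, 0, 0, 1, 1])
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        g = graph_from_edges(6, edges, labels)
        assert intra_connections(g, labels, 0) == 6
        assert intra_connections(g, labels, 1) == 0
        assert inter_connections(g, labels, 0, 1) == 0

    def test_complete_bipartite(self):
        labels = np.array([0, 0, 0, 1, 1])
        edges = [(i, j) for i in range(3) for j in range(3, 5)]
        g = graph_from_edges(5, edges, labels)
        assert inter_connections(g, labels, 0, 1) == 6

    def test_same_module_rejected(self):
        labels = np.array([0, 0, 1, 1])
        g = graph_from_edges(4, [(0, 1)], labels)
        with pytest.raises(ValueError, match="intra_connections"):
            inter_connections(g, labels, 0, 0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            n = 12
            adj = np.triu((rng.random((n, n)) < 0.4).astype(np.uint8), 1)
            adj += adj.T
            labels = rng.integers(0, 4, size=n)
            g = BinaryGraph(adj, 1.0, 1.0)
            for m in range(4):
                expected = sum(
                    adj[i, j]
                    for i in range(n)
                    for j in range(i + 1, n)
                    if labels[i] == m and labels[j] == m
                )
                assert intra_connections(g, labels, m) == expected
            for m1 in range(4):
                for m2 in range(m1 + 1, 4):
                    expected = sum(
                        adj[i, j]
                        for i in range(n)
                        for j in range(n)
                        if labels[i] == m1 and labels[j] == m2
                    )
                    assert inter_connections(g, labels, m1, m2) == expected


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(11)
    labels = default_partition(35)
    latents = rng.standard_normal((400, N_NETWORKS))
    a = 0.6
    values = np.sqrt(a) * latents[:, labels] + np.sqrt(1 - a) * rng.standard_normal((400, 35))
    return ConnMatrix(np.corrcoef(values, rowvar=False)), labels


class TestModularReport:

    def test_curves_have_ten_points(self, planted):
        conn, labels = planted
        report = modular_report(conn, labels)
        assert report.q_curve.values.size == 10
        assert len(report.msi_curves) == 7
        assert len(report.intra_curves) == 7
        assert len(report.inter_curves) == 21

    def test_edge_count_conservation(self, planted):
        conn, labels = planted
        report = modular_report(conn, labels)
        from thalmod.connectome import threshold_sweep

        graphs = threshold_sweep(conn, DEFAULT_LEVELS)
        for li, g in enumerate(graphs):
            total = sum(c.values[li] for c in report.intra_curves.values()) + sum(
                c.values[li] for c in report.inter_curves.values()
            )
            assert total == g.n_edges

    def test_node_relabeling_invariance(self, planted):
        conn, labels = planted
        perm = np.random.default_rng(5).permutation(labels.size)
        conn_p = ConnMatrix(conn.values[np.ix_(perm, perm)])
        report = modular_report(conn, labels)
        report_p = modular_report(conn_p, labels[perm])
        np.testing.assert_allclose(report.q_curve.values, report_p.q_curve.values, atol=1e-12)
        for name in NETWORKS:
            np.testing.assert_allclose(
                report.intra_curves[name].values, report_p.intra_curves[name].values
            )
            assert report.msi_curves[name].auc == pytest.approx(
                report_p.msi_curves[name].auc, abs=1e-12
            )

    def test_msi_modes(self, planted):
        conn, labels = planted
        weights = modular_report(conn, labels, msi_mode="weights")
        binary = modular_report(conn, labels, msi_mode="binary")
        # weights mode is constant across levels; binary varies
        assert np.ptp(weights.msi_curves["DMN"].values) == 0.0
        assert np.ptp(binary.msi_curves["DMN"].values) > 0.0
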