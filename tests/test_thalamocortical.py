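"""Thalamocortical network assembly, two-step thresholding, PC and WMD."""

import numpy as np
import pytest

from thalmod.connectome import BinaryGraph, ConnMatrix, proportional_threshold
from thalmod.networks import default_partition
from thalmod.preprocess import ParcelTimeSeries
from thalmod.thalamocortical import (
    build_thalamocortical,
    hub_metrics,
    participation_coefficient,
    roi_network_fc,
    two_step_threshold,
    within_module_degree_z,
)


def make_graph(n, edges, labels=None):
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(adj, 1.0, 1.0, node_partition=labels)


def random_tc_matrix(rng, n_cortical=20, positive=True):
    from thalmod.networks import NETWORKS

    x = rng.standard_normal((3 * (n_cortical + 7), n_cortical + 7))
    vals = np.corrcoef(x, rowvar=False)
    if positive:
        vals = np.abs(vals)
    np.fill_diagonal(vals, 1.0)
    labels = np.concatenate([default_partition(n_cortical), np.arange(7)])
    names = [f"c{i:03d}" for i in range(n_cortical)] + [f"tha_{n}" for n in NETWORKS]
    return ConnMatrix(vals, node_names=names, node_partition=labels)


class TestBuild:
    def test_block_consistency_and_labels(self, rng):
        labels = default_partition(21)
        cortex = rng.standard_normal((200, 21))
        ts = ParcelTimeSeries(cortex, tr_seconds=2.0)
        subdiv = rng.standard_normal((200, 7))
        tc = build_thalamocortical(ts, subdiv, labels)
        assert tc.n_nodes == 28
        from thalmod.connectome import pearson_fc

        np.testing.assert_allclose(tc.values[:21, :21], pearson_fc(ts).values, atol=1e-12)
        assert tc.node_names[21:] == [
            "tha_VIS", "tha_SMN", "tha_DAN", "tha_VAN", "tha_LIM", "tha_FPN", "tha_DMN"
        ]
        np.testing.assert_array_equal(tc.node_partition[21:], np.arange(7))

    def test_missing_subdivision_recorded(self, rng):
        labels = default_partition(21)
        ts = ParcelTimeSeries(rng.standard_normal((100, 21)), tr_seconds=2.0)
        subdiv = rng.standard_normal((100, 7))
        subdiv[:, 4] = np.nan  # absent limbic subdivision
        tc = build_thalamocortical(ts, subdiv, labels)
        assert tc.n_nodes == 27
        assert "tha_LIM" not in tc.node_names

    def test_permutation_equivariance(self, rng):
        labels = default_partition(21)
        cortex = rng.standard_normal((150, 21))
        subdiv = rng.standard_normal((150, 7))
        ts = ParcelTimeSeries(cortex, tr_seconds=2.0)
        perm = rng.permutation(21)
        ts_p = ParcelTimeSeries(cortex[:, perm], tr_seconds=2.0)
        tc = build_thalamocortical(ts, subdiv, labels)
        tc_p = build_thalamocortical(ts_p, subdiv, labels[perm])
        np.testing.assert_allclose(
            tc_p.values[:21, :21], tc.values[np.ix_(perm, perm)], atol=1e-12
        )
        np.testing.assert_allclose(tc_p.values[21:, :21], tc.values[21:, :21][:, perm],
                                   atol=1e-12)


class TestTwoStepThreshold:
    def test_full_sparsity_all_positive_gives_complete_graph(self, rng):
        tc = random_tc_matrix(rng, n_cortical=20)
        g = two_step_threshold(tc, 1.0, n_cortical=20)
        assert g.n_edges == 27 * 26 // 2

    def test_block_edge_counts_at_low_sparsity(self, rng):
        tc = random_tc_matrix(rng, n_cortical=20)
        g = two_step_threshold(tc, 0.1, n_cortical=20)
        cort = g.adjacency[:20, :20]
        thal = g.adjacency[20:, 20:]
        bip = g.adjacency[20:, :20]
        assert cort.sum() // 2 == round(0.1 * 190)
        assert thal.sum() // 2 == 2  # round(0.1 * 21)
        assert bip.sum() == 14  # round(0.1 * 140)

    def test_thal_block_full_retention_mode(self, rng):
        tc = random_tc_matrix(rng, n_cortical=20)
        g = two_step_threshold(tc, 0.1, n_cortical=20, thal_block="full")
        assert g.adjacency[20:, 20:].sum() // 2 == 21

    def test_invalid_sparsity_rejected(self, rng):
        with pytest.raises(ValueError):
            two_step_threshold(random_tc_matrix(rng), 0.0)


class TestParticipationCoefficient:
    def test_single_module_node(self):
        labels = np.array([0, 0, 0, 1, 1])
        g = make_graph(5, [(0, 1), (0, 2)])
        assert participation_coefficient(g, labels)[0] == pytest.approx(0.0)

    def test_even_two_module_split(self):
        labels = np.array([0, 0, 0, 1, 1])
        g = make_graph(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
        assert participation_coefficient(g, labels)[0] == pytest.approx(0.5)

    def test_one_edge_per_module_over_seven(self):
        labels = np.concatenate([[0], np.arange(7)])
        g = make_graph(8, [(0, j) for j in range(1, 8)])
        assert participation_coefficient(g, labels)[0] == pytest.approx(6 / 7)

    def test_isolated_node_is_zero(self):
        labels = np.array([0, 0, 1])
        g = make_graph(3, [(0, 1)])
        assert participation_coefficient(g, labels)[2] == 0.0

    def test_bounded_below_one(self, rng):
        for _ in range(20):
            n = 12
            adj = np.triu((rng.random((n, n)) < 0.5).astype(np.uint8), 1)
            adj += adj.T
            labels = rng.integers(0, 7, size=n)
            pc = participation_coefficient(BinaryGraph(adj, 1.0, 1.0), labels)
            assert (pc < 1.0).all() and (pc >= 0.0).all()


class TestWithinModuleDegree:
    def test_equal_degrees_give_zero(self):
        labels = np.array([0, 0, 0])
        g = make_graph(3, [(0, 1), (1, 2), (0, 2)])
        np.testing.assert_allclose(within_module_degree_z(g, labels), 0.0)

    def test_hand_computed_example(self):
        # module of 3 with within-degrees (2, 1, 1): z_0 = (2 - 4/3)/sqrt(2/9)
        labels = np.array([0, 0, 0, 1, 1])
        g = make_graph(5, [(0, 1), (0, 2), (3, 4)])
        z = within_module_degree_z(g, labels)
        assert z[0] == pytest.approx(np.sqrt(2), abs=1e-12)
        assert z[1] == pytest.approx(-1 / np.sqrt(2), abs=1e-12)

    def test_z_scores_sum_to_zero_within_module(self, rng):
        n = 12
        adj = np.triu((rng.random((n, n)) < 0.6).astype(np.uint8), 1)
        adj += adj.T
        labels = np.array([0] * 6 + [1] * 6)
        z = within_module_degree_z(BinaryGraph(adj, 1.0, 1.0), labels)
        assert z[:6].sum() == pytest.approx(0.0, abs=1e-10)

    def test_singleton_module_rejected(self):
        labels = np.array([0, 1, 1])
        g = make_graph(3, [(0, 1)])
        with pytest.raises(ValueError, match="singleton"):
            within_module_degree_z(g, labels)


class TestHubMetricsAndRoiFC:
    def test_curves_have_one_point_per_level(self, rng):
        tc = random_tc_matrix(rng, n_cortical=20)
        hm = hub_metrics(tc, n_cortical=20)
        assert set(hm.pc_curves) == {"VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN"}
        for name in hm.networks:
            assert hm.pc_curves[name].values.size == 10
            assert hm.wmd_curves[name].values.size == 10
        df = hm.to_dataframe("sub-x")
        assert len(df) == 70

    def test_roi_fc_identity(self, rng):
        labels = default_partition(21)
        cortex = rng.standard_normal((200, 21))
        smn = np.flatnonzero(labels == 1)
        cortex[:, smn] = cortex[:, [smn[0]]]  # all SMN parcels identical
        ts = ParcelTimeSeries(cortex, tr_seconds=2.0)
        value = roi_network_fc(cortex[:, smn[0]], ts, labels, 1)
        assert value == pytest.approx(1.0, abs=1e-6)

    def test_roi_fc_null(self, rng):
        labels = default_partition(21)
        ts = ParcelTimeSeries(rng.standard_normal((300, 21)), tr_seconds=2.0)
        vals = [
            roi_network_fc(rng.standard_normal(300), ts, labels, 1) for _ in range(40)
        ]
        assert (np.abs(vals) < 0.1).mean() >= 0.95

    def test_single_step_thresholding_drops_bipartite_edges(self, rng):
        """Motivating contrast: proportional thresholding of the full matrix
        can retain zero thalamocortical edges; the two-step scheme keeps
        exactly its block quota (full-size version in the acceptance suite)."""
        n_c = 20
        vals = np.ones((27, 27))
        rng_ = np.random.default_rng(0)
        cort = rng_.uniform(0.5, 0.9, size=(n_c, n_c))
        thal = rng_.uniform(0.4, 0.5, size=(7, 7))
        bip = rng_.uniform(0.01, 0.1, size=(7, n_c))
        vals[:n_c, :n_c] = (cort + cort.T) / 2
        vals[n_c:, n_c:] = (thal + thal.T) / 2
        vals[n_c:, :n_c] = bip
        vals[:n_c, n_c:] = bip.T
        np.fill_diagonal(vals, 1.0)
        labels = np.concatenate([default_partition(n_c), np.arange(7)])
        tc = ConnMatrix(vals, node_partition=labels)
        g2 = two_step_threshold(tc, 0.1, n_cortical=n_c)
        assert g2.adjacency[n_c:, :n_c].sum() == 14
        g1 = proportional_threshold(tc, 0.1)
        assert g1.adjacency[n_c:, :n_c].sum() == 0
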