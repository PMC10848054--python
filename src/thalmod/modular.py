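"""Modularity, modular segregation, and intra-/inter-module edge counts.

All metrics are evaluated against the *fixed* a-priori 7-network partition
(no community detection): Newman modularity Q of the binary graph, the
modular segregation index MSI(m) = (W̄ − B̄)/W̄ on positive weights, and raw
intra-/inter-module edge counts per sparsity level. A Louvain-based
detected-partition Q is available as an optional cross-check only.

MSI is computed once on the unthresholded positive-weight matrix by default
(``mode='weights'``) and replicated across levels; on binary graphs it would
be a deterministic function of edge counts. A per-level binary mode is kept
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import BinaryGraph, ConnMatrix, DEFAULT_LEVELS, MetricCurve, threshold_sweep
from .networks import NETWORKS, N_NETWORKS, module_pairs, validate_partition


def modularity_q(g: BinaryGraph, labels: np.ndarray) -> float:
    """Newman modularity of a binary graph on a given partition.

    Q = (1/2E) Σ_ij [A_ij − k_i k_j / 2E] δ(c_i, c_j).
    """
    labels = np.asarray(labels)
    adj = g.adjacency.astype(float)
    two_e = adj.sum()
    if two_e == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    k = adj.sum(axis=1)
    q = 0.0
    for m in np.unique(labels):
        idx = np.flatnonzero(labels == m)
        q += adj[np.ix_(idx, idx)].sum() / two_e - (k[idx].sum() / two_e) ** 2
    return float(q)


def detected_partition_q(g: BinaryGraph, seed: int = 0) -> tuple[float, list[set]]:
    """Louvain community detection Q (networkx) — cross-check only."""
    import networkx as nx

    graph = nx.from_numpy_array(g.adjacency)
    communities = nx.community.louvain_communities(graph, seed=seed)
    q = nx.community.modularity(graph, communities)
    return float(q), [set(c) for c in communities]


def modular_segregation_index(conn: ConnMatrix, labels: np.ndarray, module: int) -> float:
    """MSI(m) = (W̄ − B̄)/W̄ on positive weights.

    W̄ is the mean over within-module node pairs and B̄ the mean over pairs
    linking the module to every other module; negative correlations count
    as zero.
    """
    labels = np.asarray(labels)
    inside = np.flatnonzero(labels == module)
    outside = np.flatnonzero(labels != module)
    if inside.size < 2:
        raise ValueError(f"module {NETWORKS[module]} needs >= 2 nodes for MSI")
    w = np.clip(conn.values, 0.0, None)
    within = w[np.ix_(inside, inside)]
    iu = np.triu_indices(inside.size, 1)
    w_bar = within[iu].mean()
    if w_bar == 0:
        raise ValueError(f"MSI undefined: no positive within-module weight in {NETWORKS[module]}")
    b_bar = w[np.ix_(inside, outside)].mean()
    return float((w_bar - b_bar) / w_bar)


def intra_connections(g: BinaryGraph, labels: np.ndarray, module: int) -> int:
    """Number of edges with both endpoints inside ``module``."""
    idx = np.flatnonzero(np.asarray(labels) == module)
    return int(g.adjacency[np.ix_(idx, idx)].sum()) // 2


def inter_connections(g: BinaryGraph, labels: np.ndarray, m1: int, m2: int) -> int:
    """Number of edges with one endpoint in each of two distinct modules."""
    if m1 == m2:
        raise ValueError("modules are identical; use intra_connections")
    labels = np.asarray(labels)
    idx1 = np.flatnonzero(labels == m1)
    idx2 = np.flatnonzero(labels == m2)
    return int(g.adjacency[np.ix_(idx1, idx2)].sum())


@dataclass
class ModularReport:
    """Per-subject modular metrics across the sparsity sweep."""

    q_curve: MetricCurve
    msi_curves: dict[str, MetricCurve]
    intra_curves: dict[str, MetricCurve]
    inter_curves: dict[tuple[str, str], MetricCurve]

    def to_long_dataframe(self, subject_id: str = "") -> pd.DataFrame:
        rows = []

        def emit(metric: str, module: str, curve: MetricCurve) -> None:
            for level, value in zip(curve.levels, curve.values):
                rows.append((subject_id, metric, module, float(level), float(value), curve.auc))

        emit("Q", "global", self.q_curve)
        for name, curve in self.msi_curves.items():
            emit("MSI", name, curve)
        for name, curve in self.intra_curves.items():
            emit("intra", name, curve)
        for (a, b), curve in self.inter_curves.items():
            emit("inter", f"{a}-{b}", curve)
        return pd.DataFrame(
            rows, columns=["subject", "metric", "module", "level", "value", "auc"]
        )


def modular_report(
    conn: ConnMatrix,
    labels: np.ndarray | None = None,
    levels: np.ndarray = DEFAULT_LEVELS,
    msi_mode: str = "weights",
) -> ModularReport:
    """Q, MSI, and intra/inter edge-count curves with their AUCs."""
    if labels is None:
        labels = conn.node_partition
    if labels is None:
        raise ValueError("no node partition available")
    labels = np.asarray(labels)
    validate_partition(labels)
    graphs = threshold_sweep(conn, levels)
    levels = np.asarray(levels, dtype=float)

    q_vals = np.array([modularity_q(g, labels) for g in graphs])
    intra = {
        NETWORKS[m]: np.array([intra_connections(g, labels, m) for g in graphs], dtype=float)
        for m in range(N_NETWORKS)
    }
    inter = {
        (NETWORKS[m1], NETWORKS[m2]): np.array(
            [inter_connections(g, labels, m1, m2) for g in graphs], dtype=float
        )
        for m1, m2 in module_pairs()
    }
    if msi_mode == "weights":
        msi_once = {
            NETWORKS[m]: modular_segregation_index(conn, labels, m) for m in range(N_NETWORKS)
        }
        msi = {name: np.full(levels.size, v) for name, v in msi_once.items()}
    elif msi_mode == "binary":
        msi = {
            NETWORKS[m]: np.array(
                [
                    modular_segregation_index(
                        ConnMatrix(
                            g.adjacency.astype(float) - np.diag(np.diagonal(g.adjacency).astype(float)) + np.eye(g.n_nodes)
                        ),
                        labels,
                        m,
                    )
                    for g in graphs
                ]
            )
            for m in range(N_NETWORKS)
        }
    else:
        raise ValueError(f"unknown msi_mode {msi_mode!r}")

    return ModularReport(
        q_curve=MetricCurve(levels, q_vals),
        msi_curves={k: MetricCurve(levels, v) for k, v in msi.items()},
        intra_curves={k: MetricCurve(levels, v) for k, v in intra.items()},
        inter_curves={k: MetricCurve(levels, v) for k, v in inter.items()},
    )
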