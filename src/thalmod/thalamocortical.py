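"""Thalamocortical networks, two-step thresholding, and hub metrics.

The thalamocortical network concatenates the 200 cortical parcels with the
7 thalamic subdivision mean series into a 207 x 207 correlation matrix
(thalamic nodes appended after cortical nodes in the fixed network order;
each thalamic node inherits the module label of its network).

Thresholding the whole matrix proportionally would sacrifice the weaker
thalamic–cortical correlations, so the same sparsity S is applied
*independently* to the three blocks — cortical–cortical (200 x 200),
thalamo-thalamic (7 x 7) and thalamo-cortical (7 x 200) — before the binary
blocks are reassembled ("two-step thresholding"). The bipartite block thus
retains exactly round(S * 1400) edges regardless of how weak they are
relative to cortical edges.

Hub metrics for thalamic nodes on the binary graph: the participation
coefficient PC_i = 1 − Σ_m (k_im / k_i)² and the within-module degree
z-score WMD_i = (κ_i − mean κ)/sd κ over the nodes of i's module
(population SD; 0 when the SD vanishes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import (
    BinaryGraph,
    ConnMatrix,
    DEFAULT_LEVELS,
    MetricCurve,
    fisher_z,
    inverse_fisher_z,
    proportional_threshold,
    round_half_away,
)
from .networks import NETWORKS, N_NETWORKS, module_indices
from .preprocess import ParcelTimeSeries


def build_thalamocortical(
    cortical_ts: ParcelTimeSeries,
    subdivision_ts: np.ndarray,
    partition: np.ndarray,
    present: np.ndarray | None = None,
) -> ConnMatrix:
    """Pearson correlation over the concatenated cortical + thalamic regions.

    ``subdivision_ts`` is the (T, 7) subdivision matrix; absent subdivisions
    (``present`` false or NaN columns) are excluded and the exclusion is
    recorded in the node names of the result.
    """
    subdivision_ts = np.asarray(subdivision_ts, dtype=float)
    if subdivision_ts.shape[0] != cortical_ts.n_timepoints:
        raise ValueError("cortical and subdivision series must share the time axis")
    if present is None:
        present = ~np.isnan(subdivision_ts).any(axis=0)
    kept = np.flatnonzero(present)
    combined = np.column_stack([cortical_ts.values, subdivision_ts[:, kept]])
    r = np.corrcoef(combined, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    names = list(cortical_ts.region_names) + [f"tha_{NETWORKS[m]}" for m in kept]
    labels = np.concatenate([np.asarray(partition), kept])
    return ConnMatrix(r, node_names=names, node_partition=labels)


def _top_k_positive_flat(values: np.ndarray, k: int) -> np.ndarray:
    """Binary mask keeping the k largest positive entries of a 2-D block.

    Ties break by ascending (row, col) index; fewer than k positives keeps
    all positives.
    """
    rows, cols = np.indices(values.shape)
    flat_r, flat_c, flat_v = rows.ravel(), cols.ravel(), values.ravel()
    order = np.lexsort((flat_c, flat_r, -flat_v))
    n_pos = int((flat_v > 0).sum())
    keep = order[: min(k, n_pos)]
    mask = np.zeros(values.shape, dtype=np.uint8)
    mask[flat_r[keep], flat_c[keep]] = 1
    return mask


def two_step_threshold(
    tc: ConnMatrix,
    sparsity: float,
    n_cortical: int = 200,
    thal_block: str = "threshold",
) -> BinaryGraph:
    """Apply the same sparsity independently to the three blocks.

    ``thal_block='full'`` keeps every positive thalamo-thalamic correlation
    instead of thresholding that block (sensitivity mode).
    """
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    n = tc.n_nodes
    n_thal = n - n_cortical
    if n_thal <= 0:
        raise ValueError("matrix has no thalamic nodes beyond n_cortical")

    cort = ConnMatrix(tc.values[:n_cortical, :n_cortical])
    cort_adj = proportional_threshold(cort, sparsity).adjacency

    thal = ConnMatrix(tc.values[n_cortical:, n_cortical:])
    if thal_block == "full":
        thal_adj = (thal.values > 0).astype(np.uint8)
        np.fill_diagonal(thal_adj, 0)
    elif thal_block == "threshold":
        thal_adj = proportional_threshold(thal, sparsity).adjacency
    else:
        raise ValueError(f"unknown thal_block mode {thal_block!r}")

    bip = tc.values[n_cortical:, :n_cortical]  # 7 x 200
    k_c = round_half_away(sparsity * bip.size)
    bip_adj = _top_k_positive_flat(bip, k_c)

    adj = np.zeros((n, n), dtype=np.uint8)
    adj[:n_cortical, :n_cortical] = cort_adj
    adj[n_cortical:, n_cortical:] = thal_adj
    adj[n_cortical:, :n_cortical] = bip_adj
    adj[:n_cortical, n_cortical:] = bip_adj.T
    n_pairs = n * (n - 1) // 2
    return BinaryGraph(adj, sparsity=sparsity,
                       achieved_sparsity=adj.sum() / 2 / n_pairs,
                       node_partition=tc.node_partition)


def participation_coefficient(g: BinaryGraph, labels: np.ndarray) -> np.ndarray:
    """PC per node; an isolated node gets PC = 0."""
    labels = np.asarray(labels)
    adj = g.adjacency.astype(float)
    onehot = np.zeros((labels.size, N_NETWORKS))
    onehot[np.arange(labels.size), labels] = 1.0
    k_im = adj @ onehot
    k = k_im.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = 1.0 - np.nansum((k_im / k[:, None]) ** 2, axis=1)
    pc[k == 0] = 0.0
    return pc


def within_module_degree_z(g: BinaryGraph, labels: np.ndarray) -> np.ndarray:
    """WMD z-score per node (population SD within each module)."""
    labels = np.asarray(labels)
    adj = g.adjacency.astype(float)
    z = np.zeros(labels.size)
    for m in np.unique(labels):
        idx = np.flatnonzero(labels == m)
        if idx.size < 2:
            raise ValueError(f"module {NETWORKS[m]} is a singleton; WMD undefined")
        kappa = adj[np.ix_(idx, idx)].sum(axis=1)
        sd = kappa.std()  # population SD
        z[idx] = 0.0 if sd == 0 else (kappa - kappa.mean()) / sd
    return z


@dataclass
class HubMetrics:
    """PC and WMD curves (with AUCs) for the thalamic nodes."""

    networks: list[str]
    pc_curves: dict[str, MetricCurve]
    wmd_curves: dict[str, MetricCurve]

    def to_dataframe(self, subject_id: str = "") -> pd.DataFrame:
        rows = []
        for name in self.networks:
            pc, wmd = self.pc_curves[name], self.wmd_curves[name]
            for level, p, w in zip(pc.levels, pc.values, wmd.values):
                rows.append((subject_id, f"tha_{name}", float(level), float(p), float(w),
                             pc.auc, wmd.auc))
        return pd.DataFrame(
            rows,
            columns=["subject", "node", "level", "pc", "wmd", "pc_auc", "wmd_auc"],
        )


def hub_metrics(
    tc: ConnMatrix,
    levels: np.ndarray = DEFAULT_LEVELS,
    n_cortical: int = 200,
    thal_block: str = "threshold",
) -> HubMetrics:
    """Two-step threshold at each level; PC and WMD per thalamic node."""
    levels = np.asarray(levels, dtype=float)
    labels = tc.node_partition
    if labels is None:
        raise ValueError("thalamocortical matrix carries no node partition")
    thal_idx = np.arange(n_cortical, tc.n_nodes)
    thal_names = [tc.node_names[i].replace("tha_", "") for i in thal_idx]
    pc_vals = np.empty((levels.size, thal_idx.size))
    wmd_vals = np.empty((levels.size, thal_idx.size))
    for li, s in enumerate(levels):
        g = two_step_threshold(tc, s, n_cortical=n_cortical, thal_block=thal_block)
        pc_vals[li] = participation_coefficient(g, labels)[thal_idx]
        wmd_vals[li] = within_module_degree_z(g, labels)[thal_idx]
    return HubMetrics(
        networks=thal_names,
        pc_curves={n: MetricCurve(levels, pc_vals[:, i]) for i, n in enumerate(thal_names)},
        wmd_curves={n: MetricCurve(levels, wmd_vals[:, i]) for i, n in enumerate(thal_names)},
    )


def roi_network_fc(
    subdivision_series: np.ndarray,
    cortical_ts: ParcelTimeSeries,
    partition: np.ndarray,
    network: int,
) -> float:
    """Mean FC between a thalamic subdivision and its own network's parcels.

    Per-parcel Pearson correlations are averaged through the Fisher z
    transform.
    """
    subdivision_series = np.asarray(subdivision_series, dtype=float)
    if np.isnan(subdivision_series).any():
        raise ValueError("subdivision is absent (NaN series)")
    idx = module_indices(partition, network)
    if idx.size == 0:
        raise ValueError(f"network {NETWORKS[network]} has no parcels")
    x = subdivision_series - subdivision_series.mean()
    x /= x.std()
    y = cortical_ts.values[:, idx]
    y = (y - y.mean(0)) / y.std(0)
    r = np.clip((x @ y) / x.size, -1.0, 1.0)
    return float(inverse_fisher_z(np.mean(fisher_z(r))))
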