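"""Correlation matrices, proportional sparsity thresholding, and AUC curves.

Functional connectivity is the Pearson correlation between two regions'
time series. Graphs are obtained by keeping the strongest fraction S of
positive correlations ("sparsity" S swept over 0.1 … 1.0 by default), and
every graph metric is summarised threshold-free by the trapezoidal area
under its curve across the sweep.

Conventions that change edge sets on degenerate inputs, and are therefore
fixed here: the retained edge count is K = round(S·N(N−1)/2) with halves
rounded away from zero; ties on equal correlation break by ascending (i, j)
index pair; negative correlations are never admitted as edges (if fewer
than K positive entries exist, all positive entries are kept and the
achieved sparsity is recorded).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import ParcelTimeSeries

#: Default sparsity sweep: 0.1 to 1.0 in steps of 0.1.
DEFAULT_LEVELS: np.ndarray = np.round(np.arange(1, 11) * 0.1, 10)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ConnMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    node_names: list[str] = field(default_factory=list)
    node_partition: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        np.fill_diagonal(v, 1.0)
        self.values = v
        if not self.node_names:
            self.node_names = [f"node{i:03d}" for i in range(v.shape[0])]
        if len(self.node_names) != v.shape[0]:
            raise ValueError("node_names length mismatch")
        if self.node_partition is not None:
            self.node_partition = np.asarray(self.node_partition)
            if self.node_partition.shape[0] != v.shape[0]:
                raise ValueError("node_partition length mismatch")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryGraph:
    """Undirected binary adjacency at a given sparsity level."""

    adjacency: np.ndarray
    sparsity: float
    achieved_sparsity: float
    node_partition: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if (a != a.T).any() or np.diagonal(a).any():
            raise ValueError("adjacency must be symmetric with zero diagonal")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass
class MetricCurve:
    """A graph metric evaluated across the sparsity sweep, with its AUC."""

    levels: np.ndarray
    values: np.ndarray
    auc: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.levels.shape != self.values.shape:
            raise ValueError("levels and values must have the same length")
        if self.auc is None:
            self.auc = auc(self.values, self.levels)


def pearson_fc(ts: ParcelTimeSeries, node_partition: np.ndarray | None = None) -> ConnMatrix:
    """Pearson correlation between all region pairs; diagonal set to 1."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    sd = ts.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.region_names[i] for i in dead[:5])
        raise ValueError(f"zero-variance region(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnMatrix(r, node_names=list(ts.region_names), node_partition=node_partition)


def fisher_z(r):
    """atanh transform; |r| >= 1 is clipped to ±(1−1e−7) with a warning."""
    r = np.asarray(r, dtype=float)
    if (np.abs(r) >= 1).any():
        warnings.warn("|r| >= 1 clipped before Fisher z transform", stacklevel=2)
        r = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    """tanh, the inverse of :func:`fisher_z`."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def _ranked_upper_triangle(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle entries ranked by descending value, ties by (i, j)."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = values[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order], vals[order]


def proportional_threshold(conn: ConnMatrix, sparsity: float) -> BinaryGraph:
    """Keep the top K = round(S·N(N−1)/2) positive correlations as edges."""
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    iu, ju, vals = _ranked_upper_triangle(conn.values)
    n_pairs = vals.size
    k = round_half_away(sparsity * n_pairs)
    n_pos = int((vals > 0).sum())  # positives form a prefix of the ranking
    keep = min(k, n_pos)
    adj = np.zeros_like(conn.values, dtype=np.uint8)
    adj[iu[:keep], ju[:keep]] = 1
    adj |= adj.T
    achieved = keep / n_pairs if n_pairs else 0.0
    return BinaryGraph(adj, sparsity=sparsity, achieved_sparsity=achieved,
                       node_partition=conn.node_partition)


def threshold_sweep(conn: ConnMatrix, levels: np.ndarray = DEFAULT_LEVELS) -> list[BinaryGraph]:
    """One graph per sparsity level; edge sets are nested across levels."""
    levels = np.asarray(levels, dtype=float)
    if (np.diff(levels) <= 0).any():
        raise ValueError("levels must be strictly increasing")
    if levels.min() <= 0 or levels.max() > 1:
        raise ValueError("levels must lie in (0, 1]")
    return [proportional_threshold(conn, s) for s in levels]


def auc(values: np.ndarray, levels: np.ndarray) -> float:
    """Trapezoidal integral of a metric curve over the sparsity axis."""
    values = np.asarray(values, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if values.shape != levels.shape:
        raise ValueError("values and levels must have the same length")
    if levels.size < 2:
        raise ValueError("need at least 2 levels for an AUC")
    return float(np.trapezoid(values, levels))
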