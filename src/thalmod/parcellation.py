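"""Winner-take-all functional parcellation of thalamic voxels.

Each in-mask thalamic voxel is labelled with the cortical network whose
seed time series (the mean over that network's parcels) correlates most
strongly with the voxel. Seed-to-voxel maps are averaged across subjects
through the Fisher z transform before labelling. Ties break by the fixed
network order (first network wins) and voxels whose best correlation is
non-positive are labelled by the argmax anyway but flagged — both policies
emit warnings since they indicate a degenerate map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import fisher_z, inverse_fisher_z
from .networks import NETWORKS, N_NETWORKS, module_indices
from .preprocess import ParcelTimeSeries

MASK_THRESHOLD = 0.10


def mask_from_probability(prob: np.ndarray, threshold: float = MASK_THRESHOLD) -> np.ndarray:
    """Boolean in-mask volume: probability strictly greater than threshold."""
    prob = np.asarray(prob, dtype=float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability volume must lie in [0, 1]")
    return prob > threshold


@dataclass
class SeedFCMap:
    """7 x V matrix of network-seed-to-voxel Pearson correlations."""

    values: np.ndarray                    # (7, V)
    voxel_coords: np.ndarray              # (V, 3)
    networks: tuple[str, ...] = NETWORKS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords)
        if self.values.shape[0] != N_NETWORKS:
            raise ValueError("seed FC map must have one row per network")
        if self.values.shape[1] != self.voxel_coords.shape[0]:
            raise ValueError("column count must equal in-mask voxel count")
        if np.abs(self.values).max(initial=0) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class ThalamicLabelMap:
    """Per-voxel winning network, its correlation, and per-label counts."""

    labels: np.ndarray                    # (V,) winning network index
    winning_fc: np.ndarray                # (V,) correlation of the winner
    voxel_coords: np.ndarray              # (V, 3)
    nonpositive_winner: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.nonpositive_winner is None:
            self.nonpositive_winner = np.zeros(self.labels.shape, dtype=bool)

    @property
    def voxel_counts(self) -> dict[str, int]:
        return {name: int((self.labels == m).sum()) for m, name in enumerate(NETWORKS)}

    def to_volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Labels as a volume: 1..7 in-mask, 0 background."""
        vol = np.zeros(shape, dtype=np.int16)
        for (x, y, z), lab in zip(self.voxel_coords, self.labels):
            vol[x, y, z] = lab + 1
        return vol


def seed_fc_map(
    cortical_ts: ParcelTimeSeries,
    partition: np.ndarray,
    thalamic_ts: np.ndarray,
    voxel_coords: np.ndarray,
) -> SeedFCMap:
    """Seed-to-voxel correlation map for one subject.

    The seed signal of each network is the mean of its parcels' time series.
    """
    thalamic_ts = np.asarray(thalamic_ts, dtype=float)
    if thalamic_ts.shape[0] != cortical_ts.n_timepoints:
        raise ValueError("cortical and thalamic series must share the time axis")
    if thalamic_ts.shape[1] == 0:
        raise ValueError("empty thalamic mask")
    seeds = np.empty((cortical_ts.n_timepoints, N_NETWORKS))
    for m in range(N_NETWORKS):
        idx = module_indices(partition, m)
        if idx.size == 0:
            raise ValueError(f"network {NETWORKS[m]} has no parcels")
        seeds[:, m] = cortical_ts.values[:, idx].mean(axis=1)

    # Pearson r between each seed and each voxel
    s = (seeds - seeds.mean(0)) / seeds.std(0)
    v = thalamic_ts - thalamic_ts.mean(0)
    sd = v.std(0)
    if (sd == 0).any():
        raise ValueError("zero-variance thalamic voxel")
    v /= sd
    r = (s.T @ v) / seeds.shape[0]
    return SeedFCMap(np.clip(r, -1.0, 1.0), voxel_coords)


def group_average_fc(maps: list[SeedFCMap], use_fisher: bool = True) -> SeedFCMap:
    """Average seed-to-voxel maps across subjects (Fisher z by default)."""
    if not maps:
        raise ValueError("no maps to average")
    coords = maps[0].voxel_coords
    for m in maps[1:]:
        if m.values.shape != maps[0].values.shape or not np.array_equal(m.voxel_coords, coords):
            raise ValueError("seed FC maps cover different voxel sets")
    stack = np.stack([m.values for m in maps])
    if use_fisher:
        mean = inverse_fisher_z(np.mean(fisher_z(stack), axis=0))
    else:
        mean = stack.mean(axis=0)
    return SeedFCMap(mean, coords)


def winner_take_all(fc_map: SeedFCMap) -> ThalamicLabelMap:
    """Label each voxel with the network of its strongest correlation."""
    values = fc_map.values
    labels = np.argmax(values, axis=0)  # argmax returns the first maximum: fixed-order tie rule
    winning = values[labels, np.arange(values.shape[1])]
    ties = (values == winning[None, :]).sum(axis=0) > 1
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} voxel(s) had tied winning correlations; "
            "first network in fixed order wins",
            stacklevel=2,
        )
    nonpos = winning <= 0
    if nonpos.any():
        warnings.warn(
            f"{int(nonpos.sum())} voxel(s) have a non-positive winning correlation",
            stacklevel=2,
        )
    return ThalamicLabelMap(labels, winning, fc_map.voxel_coords, nonpositive_winner=nonpos)


def subdivision_timeseries(
    thalamic_ts: np.ndarray, label_map: ThalamicLabelMap
) -> tuple[np.ndarray, np.ndarray]:
    """Mean time series per thalamic subdivision.

    Returns a (T, 7) matrix and a boolean presence mask; a column whose
    subdivision has no voxels is NaN and flagged absent.
    """
    thalamic_ts = np.asarray(thalamic_ts, dtype=float)
    out = np.full((thalamic_ts.shape[0], N_NETWORKS), np.nan)
    present = np.zeros(N_NETWORKS, dtype=bool)
    for m in range(N_NETWORKS):
        idx = np.flatnonzero(label_map.labels == m)
        if idx.size:
            out[:, m] = thalamic_ts[:, idx].mean(axis=1)
            present[m] = True
    return out, present


def parcellate_cohort(
    subjects_cortical: list[ParcelTimeSeries],
    partition: np.ndarray,
    subjects_thalamic: list[np.ndarray],
    voxel_coords: np.ndarray,
    use_fisher: bool = True,
) -> ThalamicLabelMap:
    """Group-level winner-take-all labels from all subjects' seed maps."""
    maps = [
        seed_fc_map(ts, partition, thal, voxel_coords)
        for ts, thal in zip(subjects_cortical, subjects_thalamic)
    ]
    return winner_take_all(group_average_fc(maps, use_fisher=use_fisher))
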