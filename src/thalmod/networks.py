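"""The fixed 7-network cortical partition.

Every metric in this package is referenced to an a-priori partition of the
cortex into seven canonical resting-state networks (visual, somatomotor,
dorsal attention, ventral attention, limbic, frontoparietal, default mode).
Nodes carry integer module labels indexing into :data:`NETWORKS`; the order
is fixed and doubles as the tie-break order for winner-take-all labelling.
"""

from __future__ import annotations

import numpy as np

#: Fixed module order. Index into this tuple is the integer label used
#: throughout the package.
NETWORKS: tuple[str, ...] = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN")

NETWORK_INDEX: dict[str, int] = {name: i for i, name in enumerate(NETWORKS)}

N_NETWORKS = len(NETWORKS)

# Parcel counts per network for the default 200-parcel cortical atlas,
# proportioned like the canonical 7-network assignment (DMN largest).
_DEFAULT_COUNTS_200 = (30, 32, 26, 24, 12, 30, 46)


def default_partition(n_parcels: int = 200) -> np.ndarray:
    """Integer module label per parcel for an ``n_parcels``-region cortex.

    For 200 parcels the canonical counts are used directly; for other sizes
    the counts are scaled proportionally (largest-remainder rounding) with at
    least one parcel per module. Labels are assigned in contiguous blocks in
    the fixed network order.
    """
    if n_parcels < N_NETWORKS:
        raise ValueError(
            f"need at least {N_NETWORKS} parcels to cover all networks, got {n_parcels}"
        )
    if n_parcels == 200:
        counts = list(_DEFAULT_COUNTS_200)
    else:
        fractions = np.asarray(_DEFAULT_COUNTS_200, dtype=float) / 200.0
        raw = fractions * n_parcels
        # at least 2 parcels per module where possible, so per-module metrics
        # (segregation index, within-module degree) stay defined
        floor = 2 if n_parcels >= 2 * N_NETWORKS else 1
        counts = np.maximum(np.floor(raw).astype(int), floor)
        remainder = raw - np.floor(raw)
        # hand out the leftover parcels to the largest remainders
        short = n_parcels - int(counts.sum())
        if short < 0:  # floors + the >=1 clamp overshot; trim largest modules
            for _ in range(-short):
                counts[int(np.argmax(counts))] -= 1
        else:
            for idx in np.argsort(-remainder)[:short]:
                counts[idx] += 1
        counts = list(counts)
    labels = np.repeat(np.arange(N_NETWORKS), counts)
    return labels


def validate_partition(labels: np.ndarray, require_all: bool = True) -> None:
    """Raise ``ValueError`` if labels are not a valid 7-network partition."""
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValueError("partition labels must be a 1-D array")
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= N_NETWORKS:
        raise ValueError("partition labels must be integers in [0, 7)")
    if require_all:
        missing = set(range(N_NETWORKS)) - set(np.unique(labels).tolist())
        if missing:
            names = ", ".join(NETWORKS[m] for m in sorted(missing))
            raise ValueError(f"partition is missing modules: {names}")


def module_indices(labels: np.ndarray, module: int) -> np.ndarray:
    """Node indices belonging to ``module``."""
    return np.flatnonzero(np.asarray(labels) == module)


def label_names(labels: np.ndarray) -> list[str]:
    return [NETWORKS[m] for m in np.asarray(labels)]


def module_pairs() -> list[tuple[int, int]]:
    """All 21 unordered module pairs in fixed order."""
    return [(i, j) for i in range(N_NETWORKS) for j in range(i + 1, N_NETWORKS)]
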