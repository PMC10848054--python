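"""Temporal preprocessing of parcel/voxel time series and motion exclusion.

Implements the temporal half of a standard resting-state pipeline: dropping
initial volumes, linear detrending, zero-phase band-pass filtering
(0.01–0.08 Hz by default), and nuisance regression against a Friston-24 +
white-matter + CSF design. Image-space steps (realignment, normalisation,
smoothing) are out of scope; inputs are already parcel-level matrices.

The canonical stage order is drop → detrend → band-pass → regress; the
pipeline runner refuses any other order unless explicitly overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

DEFAULT_ORDER = ("drop", "detrend", "bandpass", "regress")

#: Subject-level motion exclusion thresholds: maximum translation (mm),
#: maximum rotation (degrees), mean framewise displacement (mm).
MAX_TRANSLATION_MM = 3.0
MAX_ROTATION_DEG = 3.0
MAX_MEAN_FD_MM = 0.2


@dataclass
class ParcelTimeSeries:
    """A time × region numeric matrix with repetition-time metadata."""

    values: np.ndarray
    tr_seconds: float
    region_names: list[str] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (time x region) matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains missing/non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.region_names:
            self.region_names = [f"region{i:03d}" for i in range(self.values.shape[1])]
        if len(self.region_names) != self.values.shape[1]:
            raise ValueError("region_names length does not match region count")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class MotionSummary:
    """Per-subject head-motion summary used for exclusion decisions."""

    max_translation_mm: float
    max_rotation_deg: float
    mean_fd_mm: float

    def __post_init__(self) -> None:
        for name in ("max_translation_mm", "max_rotation_deg", "mean_fd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def drop_initial_volumes(ts: ParcelTimeSeries, k: int = 10) -> ParcelTimeSeries:
    """Remove the first ``k`` volumes (signal-stabilisation discard)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= ts.n_timepoints:
        raise ValueError(
            f"cannot drop {k} volumes from a series of length {ts.n_timepoints}"
        )
    return replace(ts, values=ts.values[k:].copy(), n_dropped=ts.n_dropped + k)


def motion_exclude(m: MotionSummary) -> bool:
    """True if the subject should be excluded for excessive head motion.

    Exclusion when translation exceeds 3 mm, rotation exceeds 3 degrees, or
    mean framewise displacement exceeds 0.2 mm (all strict inequalities).
    """
    return (
        m.max_translation_mm > MAX_TRANSLATION_MM
        or m.max_rotation_deg > MAX_ROTATION_DEG
        or m.mean_fd_mm > MAX_MEAN_FD_MM
    )


def framewise_displacement(motion6: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style FD from 6 rigid-body parameters (3 transl. mm, 3 rot. rad).

    FD_t = sum |Δtranslation| + head_radius · sum |Δrotation|; FD_0 = 0.
    """
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError("motion matrix must be time x 6")
    d = np.diff(motion6, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def detrend_linear(ts: ParcelTimeSeries) -> ParcelTimeSeries:
    """Subtract the per-column least-squares line (intercept + slope·t)."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints to detrend")
    values = signal.detrend(ts.values, axis=0, type="linear")
    return replace(ts, values=values)


def bandpass(
    ts: ParcelTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 4,
    method: str = "butterworth",
) -> ParcelTimeSeries:
    """Zero-phase band-pass filter applied per column.

    ``method='butterworth'`` (default) uses a forward-backward Butterworth
    filter of the given order; ``method='fft'`` applies an ideal brick-wall
    filter in the frequency domain for cross-checking.
    """
    fs = 1.0 / ts.tr_seconds
    nyquist = fs / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high cutoff {high_hz} Hz is at or above Nyquist {nyquist} Hz for TR={ts.tr_seconds}s"
        )
    if method == "butterworth":
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
        values = signal.sosfiltfilt(sos, ts.values, axis=0)
    elif method == "fft":
        freqs = np.fft.rfftfreq(ts.n_timepoints, d=ts.tr_seconds)
        spectrum = np.fft.rfft(ts.values, axis=0)
        keep = (freqs >= low_hz) & (freqs <= high_hz)
        spectrum[~keep] = 0.0
        values = np.fft.irfft(spectrum, n=ts.n_timepoints, axis=0)
    else:
        raise ValueError(f"unknown band-pass method {method!r}")
    return replace(ts, values=np.ascontiguousarray(values))


def regress_nuisance(ts: ParcelTimeSeries, regressors: np.ndarray) -> ParcelTimeSeries:
    """OLS residuals of each column against the regressors (plus intercept).

    Residuals are orthogonal to every regressor column. A rank-deficient
    design triggers a warning; the pseudoinverse projection used here equals
    dropping the dependent columns.
    """
    regressors = np.asarray(regressors, dtype=float)
    if regressors.ndim != 2 or regressors.shape[0] != ts.n_timepoints:
        raise ValueError("regressor rows must equal the time-series length")
    design = np.column_stack([np.ones(ts.n_timepoints), regressors])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            f"nuisance design is rank deficient ({rank}/{design.shape[1]}); "
            "dependent columns contribute nothing",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    residuals = ts.values - design @ beta
    return replace(ts, values=residuals)


def friston24(motion6: np.ndarray) -> np.ndarray:
    """Friston-24 expansion of 6 rigid-body parameters.

    Columns: the 6 parameters, their one-volume lags, and the squares of
    both (6 + 6 + 6 + 6 = 24). Lagged rows are zero-padded at t=0.
    """
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError("motion matrix must be time x 6")
    lagged = np.vstack([np.zeros((1, 6)), motion6[:-1]])
    return np.column_stack([motion6, lagged, motion6**2, lagged**2])


def run_temporal_pipeline(
    ts: ParcelTimeSeries,
    nuisance: np.ndarray | None = None,
    n_drop: int = 0,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    steps: tuple[str, ...] = DEFAULT_ORDER,
    allow_reorder: bool = False,
) -> ParcelTimeSeries:
    """Run the temporal pipeline in the canonical order.

    ``steps`` may omit stages but must preserve the canonical relative order
    (drop → detrend → bandpass → regress) unless ``allow_reorder`` is set.
    The nuisance matrix must span the *post-drop* time axis.
    """
    canonical = [s for s in DEFAULT_ORDER if s in steps]
    if list(steps) != canonical and not allow_reorder:
        raise ValueError(
            f"non-canonical stage order {steps}; pass allow_reorder=True to override"
        )
    for step in steps:
        if step == "drop":
            ts = drop_initial_volumes(ts, n_drop)
        elif step == "detrend":
            ts = detrend_linear(ts)
        elif step == "bandpass":
            ts = bandpass(ts, low_hz=low_hz, high_hz=high_hz)
        elif step == "regress":
            if nuisance is None:
                raise ValueError("regress step requested but no nuisance matrix given")
            ts = regress_nuisance(ts, nuisance)
        else:
            raise ValueError(f"unknown pipeline step {step!r}")
    return ts
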