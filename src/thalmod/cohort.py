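"""Synthetic cohort generator with planted modular structure.

Emulates a three-group resting-state study (healthy controls, patients with
normal cognition, patients with cognitive impairment): per-subject cortical
parcel time series with a block correlation structure following the fixed
7-network partition, thalamic voxel series each coupled to one network's
latent signal, motion/nuisance regressors, a probabilistic thalamus mask,
and a phenotype table. Every downstream stage of the package can therefore
be validated against known ground truth.

Generative model (per subject)
------------------------------
Seven unit-variance latent network signals are drawn with pairwise latent
correlation ``between_coupling``. A parcel of module m is

    x = sqrt(a) * latent_m + sqrt(1 - a) * noise,      a = within_coupling,

so the expected within-module correlation equals ``a`` analytically and the
expected between-module correlation is sqrt(a_m a_n) * b_mn. A thalamic
voxel assigned to network n mixes its own latent with the other networks'
latents according to a diffusivity d (0 = couples only to its own network),

    base  = sqrt(1 - d) * latent_n + sqrt(d/6) * sum_{m != n} latent_m
    voxel = sqrt(c) * base/sd(base)
            + sqrt(1 - c) * (sqrt(rho) * eta_n + sqrt(1 - rho) * eps),

where c = thal_coupling and eta_n is a noise component shared by all voxels
of network n (fraction ``thal_noise_shared`` = rho). The shared component
emulates spatially correlated thalamic noise; without it the voxel-level
coupling strength would cancel out of subdivision-mean time series.

Subject-level heterogeneity enters through two independent draws: a
truncated-normal multiplicative scale on the coupling strength c and an
additive normal shift of the diffusivity d. The subject's scalar
somatomotor-thalamic coupling (strength + spread, c_SMN + d_SMN) drives the
MoCA score through ``moca_model`` (intercept + slope * coupling + noise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import NETWORKS, NETWORK_INDEX, N_NETWORKS, default_partition, validate_partition
from .preprocess import ParcelTimeSeries, framewise_displacement, friston24

GROUPS = ("HC", "TLE-CN", "TLE-CI")

#: Thalamic voxel fractions per network for the synthetic thalamus
#: (default-mode subdivision largest, mirroring the known dominance of
#: default-mode coupling in the thalamus).
_THAL_FRACTIONS = np.array([24, 36, 24, 24, 18, 30, 60], dtype=float) / 216.0

#: Demographic marginals per group used by the generator: age mean/SD,
#: male fraction, education mean/SD (years), and — for patient groups —
#: onset-age mean/SD, median duration (years), median seizure rate
#: (per month), and monotherapy fraction.
DEMOGRAPHICS = {
    "HC": dict(age=(29.57, 7.75), male_frac=16 / 37, education=(13.8, 2.0)),
    "TLE-CN": dict(
        age=(29.49, 7.92), male_frac=8 / 35, education=(13.8, 2.0),
        onset_age=(19.03, 9.40), duration_median=10.5, seizure_median=1.0,
        mono_frac=16 / 35,
    ),
    "TLE-CI": dict(
        age=(33.39, 9.47), male_frac=6 / 18, education=(13.0, 2.0),
        onset_age=(25.61, 10.32), duration_median=6.0, seizure_median=0.5,
        mono_frac=10 / 18,
    ),
}

#: MoCA clip range per group; patients are classified by the < 26 cutoff,
#: so by construction impaired patients score 0–25 and intact ones 26–30.
_MOCA_RANGE = {"HC": (20, 30), "TLE-CN": (26, 30), "TLE-CI": (0, 25)}


def _uniform(value: float) -> dict[str, float]:
    return {name: float(value) for name in NETWORKS}


@dataclass
class CohortSpec:
    """Study conditions for :func:`generate_cohort`.

    Coupling dictionaries map group -> network -> value in [0, 1).
    ``between_coupling`` maps group -> latent pairwise correlation (a single
    float applied to every module pair, or a dict keyed by "M1-M2" names).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 25, "TLE-CN": 25, "TLE-CI": 25}
    )
    n_timepoints: int = 300
    tr_seconds: float = 2.0
    n_parcels: int = 200
    partition: np.ndarray | None = None
    thal_grid: tuple[int, int, int] = (6, 6, 6)
    within_coupling: dict = field(default_factory=dict)
    between_coupling: dict = field(default_factory=dict)
    thal_coupling: dict = field(default_factory=dict)
    thal_diffusivity: dict = field(default_factory=dict)
    thal_noise_shared: float = 0.65
    coupling_jitter_sd: float = 0.04
    diffusivity_spread: float = 0.20
    moca_model: dict = field(default_factory=dict)
    mirror_hemispheres: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.partition is None:
            self.partition = default_partition(self.n_parcels)
        self.partition = np.asarray(self.partition)

    def groups(self) -> list[str]:
        return [g for g in GROUPS if self.n_per_group.get(g, 0) > 0]

    def between_matrix(self, group: str) -> np.ndarray:
        """7x7 latent correlation matrix for a group."""
        b = self.between_coupling.get(group, 0.0)
        lam = np.eye(N_NETWORKS)
        if isinstance(b, dict):
            for key, value in b.items():
                m1, m2 = key.split("-")
                i, j = NETWORK_INDEX[m1], NETWORK_INDEX[m2]
                lam[i, j] = lam[j, i] = float(value)
        else:
            lam[~np.eye(N_NETWORKS, dtype=bool)] = float(b)
        return lam

    def to_dict(self) -> dict:
        d = {
            "n_per_group": dict(self.n_per_group),
            "n_timepoints": self.n_timepoints,
            "tr_seconds": self.tr_seconds,
            "n_parcels": self.n_parcels,
            "partition": self.partition.tolist(),
            "thal_grid": list(self.thal_grid),
            "within_coupling": self.within_coupling,
            "between_coupling": self.between_coupling,
            "thal_coupling": self.thal_coupling,
            "thal_diffusivity": self.thal_diffusivity,
            "thal_noise_shared": self.thal_noise_shared,
            "coupling_jitter_sd": self.coupling_jitter_sd,
            "diffusivity_spread": self.diffusivity_spread,
            "moca_model": {g: list(v) for g, v in self.moca_model.items()},
            "mirror_hemispheres": self.mirror_hemispheres,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "partition" in d and d["partition"] is not None:
            d["partition"] = np.asarray(d["partition"])
        if "thal_grid" in d:
            d["thal_grid"] = tuple(d["thal_grid"])
        if "moca_model" in d:
            d["moca_model"] = {g: tuple(v) for g, v in d["moca_model"].items()}
        return cls(**d)


def patient_between_coupling(b_affected: float = 0.19, b_other: float = 0.20,
                             affected: tuple[str, ...] = ("VAN", "DMN")) -> dict[str, float]:
    """Pairwise latent couplings for patients: pairs touching an affected
    network sit just below that network's weakened within-coupling."""
    out = {}
    for i, m1 in enumerate(NETWORKS):
        for m2 in NETWORKS[i + 1:]:
            out[f"{m1}-{m2}"] = b_affected if (m1 in affected or m2 in affected) else b_other
    return out


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The canonical study conditions.

    Controls have homogeneous within-module coupling 0.6 and uniform latent
    between-coupling 0.2. Both patient groups carry a ventral-attention and
    default-mode within-coupling deficit (0.20, with the latent couplings of
    pairs touching those networks at 0.19): the affected networks' internal
    correlations sink to the level of their external ones, which is what
    degrades binary-graph modularity and the segregation index. Thalamic
    couplings: 0.5 to every network in controls; both patient groups have a
    lowered default-mode thalamic coupling (0.35); the impaired group
    additionally has an elevated and more diffuse somatomotor thalamic
    coupling (c = 0.90, d = 0.20 vs 0.15), and its MoCA score rises with the
    subject-level somatomotor thalamic coupling (strength + spread).
    """
    within_hc = _uniform(0.60)
    within_tle = _uniform(0.60)
    within_tle["VAN"] = 0.20
    within_tle["DMN"] = 0.20
    between_tle = patient_between_coupling()
    thal_hc = _uniform(0.50)
    thal_cn = _uniform(0.50)
    thal_cn["SMN"] = 0.60
    thal_cn["DMN"] = 0.35
    thal_ci = _uniform(0.50)
    thal_ci["SMN"] = 0.90
    thal_ci["DMN"] = 0.35
    diff_hc = _uniform(0.15)
    diff_cn = _uniform(0.15)
    diff_ci = _uniform(0.15)
    diff_ci["SMN"] = 0.20
    spec = CohortSpec(
        within_coupling={"HC": within_hc, "TLE-CN": dict(within_tle), "TLE-CI": dict(within_tle)},
        between_coupling={"HC": 0.2, "TLE-CN": dict(between_tle), "TLE-CI": dict(between_tle)},
        thal_coupling={"HC": thal_hc, "TLE-CN": thal_cn, "TLE-CI": thal_ci},
        thal_diffusivity={"HC": diff_hc, "TLE-CN": diff_cn, "TLE-CI": diff_ci},
        moca_model={
            "HC": (28.84, 0.0, 1.34),
            "TLE-CN": (28.14, 0.0, 1.19),
            "TLE-CI": (3.9, 16.0, 0.6),
        },
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(spec, key, value)
    return spec


def validate_spec(spec: CohortSpec) -> None:
    """Raise ``ValueError`` on invalid study conditions."""
    if spec.n_timepoints < 60:
        raise ValueError("n_timepoints must be >= 60")
    validate_partition(spec.partition)
    if spec.partition.shape[0] != spec.n_parcels:
        raise ValueError("partition length must equal n_parcels")
    if not 0 <= spec.thal_noise_shared < 1:
        raise ValueError("thal_noise_shared must be in [0, 1)")
    for group in spec.groups():
        within = spec.within_coupling.get(group, {})
        for name, a in within.items():
            if not 0 <= a < 1:
                raise ValueError(f"within_coupling[{group}][{name}] = {a} outside [0, 1)")
        lam = spec.between_matrix(group)
        for i in range(N_NETWORKS):
            for j in range(i + 1, N_NETWORKS):
                b = lam[i, j]
                if not 0 <= b < 1:
                    raise ValueError(
                        f"between_coupling[{group}][{NETWORKS[i]}-{NETWORKS[j]}] = {b} outside [0, 1)"
                    )
                limit = min(within.get(NETWORKS[i], 1.0), within.get(NETWORKS[j], 1.0))
                if b > 0 and b >= limit:  # b = 0 (independent latents) is always valid
                    raise ValueError(
                        f"between_coupling[{group}][{NETWORKS[i]}-{NETWORKS[j]}] = {b} "
                        f"must be < min within_coupling of the pair ({limit})"
                    )
        for table_name, table in (
            ("thal_coupling", spec.thal_coupling),
            ("thal_diffusivity", spec.thal_diffusivity),
        ):
            for name, c in table.get(group, {}).items():
                if not 0 <= c < 1:
                    raise ValueError(f"{table_name}[{group}][{name}] = {c} outside [0, 1)")


# ---------------------------------------------------------------------------
# synthetic thalamus geometry


@dataclass
class ThalamusGeometry:
    """Synthetic rectangular two-hemisphere thalamus on a small 3-D grid."""

    prob_volume: np.ndarray          # probability of being thalamus, in [0, 1]
    voxel_coords: np.ndarray         # (V, 3) integer coords of in-mask voxels
    true_labels: np.ndarray          # (V,) network label per in-mask voxel
    hemisphere: np.ndarray           # (V,) 0 = left, 1 = right
    mirror_index: np.ndarray         # (V,) index of the mirrored voxel

    @property
    def n_voxels(self) -> int:
        return self.voxel_coords.shape[0]

    def label_volume(self) -> np.ndarray:
        """Network labels as a volume: 1..7 in-mask, 0 background."""
        vol = np.zeros(self.prob_volume.shape, dtype=np.int16)
        for (x, y, z), lab in zip(self.voxel_coords, self.true_labels):
            vol[x, y, z] = lab + 1
        return vol


def make_thalamus(thal_grid: tuple[int, int, int] = (6, 6, 6)) -> ThalamusGeometry:
    """Two mirrored rectangular voxel blocks inside a padded probability map.

    In-block probability is 0.9 (> the 10% mask threshold), a one-voxel
    shell around each block sits at 0.05 (below threshold), elsewhere 0.
    Network labels tile each hemisphere in contiguous runs proportional to
    :data:`_THAL_FRACTIONS`, and the right hemisphere mirrors the left.
    """
    gx, gy, gz = thal_grid
    pad, gap = 1, 2
    shape = (2 * gx + 2 * pad + gap, gy + 2 * pad, gz + 2 * pad)
    prob = np.zeros(shape)
    left = (slice(pad, pad + gx), slice(pad, pad + gy), slice(pad, pad + gz))
    right = (slice(pad + gx + gap, pad + 2 * gx + gap), slice(pad, pad + gy), slice(pad, pad + gz))
    for block in (left, right):
        xs = slice(max(block[0].start - 1, 0), block[0].stop + 1)
        ys = slice(max(block[1].start - 1, 0), block[1].stop + 1)
        zs = slice(max(block[2].start - 1, 0), block[2].stop + 1)
        prob[xs, ys, zs] = np.maximum(prob[xs, ys, zs], 0.05)
    prob[left] = 0.9
    prob[right] = 0.9

    n_hemi = gx * gy * gz
    raw = _THAL_FRACTIONS * n_hemi
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    for idx in np.argsort(-(raw - np.floor(raw)))[: n_hemi - counts.sum()]:
        counts[idx] += 1
    while counts.sum() > n_hemi:
        counts[int(np.argmax(counts))] -= 1
    hemi_labels = np.repeat(np.arange(N_NETWORKS), counts)

    left_coords = np.argwhere(prob >= 0.9)
    left_coords = left_coords[left_coords[:, 0] < pad + gx]
    order = np.lexsort((left_coords[:, 2], left_coords[:, 1], left_coords[:, 0]))
    left_coords = left_coords[order]
    x_mirror = shape[0] - 1  # mirror plane: x -> (2*pad + 2*gx + gap - 1) - x
    right_coords = left_coords.copy()
    right_coords[:, 0] = x_mirror - left_coords[:, 0]

    coords = np.vstack([left_coords, right_coords])
    labels = np.concatenate([hemi_labels, hemi_labels])
    hemisphere = np.concatenate([np.zeros(n_hemi, dtype=int), np.ones(n_hemi, dtype=int)])
    mirror_index = np.concatenate([np.arange(n_hemi) + n_hemi, np.arange(n_hemi)])
    return ThalamusGeometry(prob, coords, labels, hemisphere, mirror_index)


# ---------------------------------------------------------------------------
# subjects


@dataclass
class SubjectRecord:
    """One phenotype row: group membership, demographics, clinical features."""

    subject_id: str
    group: str
    age: float
    sex: str
    education: float
    moca: int
    onset_age: float | None = None
    duration: float | None = None
    seizure_freq: float | None = None
    aed: str | None = None


@dataclass
class SyntheticSubject:
    """One subject's simulated data plus the generator's ground truth."""

    record: SubjectRecord
    cortical_ts: ParcelTimeSeries
    thalamic_ts: np.ndarray            # time x V, in-mask voxel series
    nuisance: np.ndarray               # time x 26 (Friston-24 + WM + CSF)
    fd: np.ndarray                     # per-volume framewise displacement
    true_voxel_labels: np.ndarray      # (V,) planted network label per voxel
    thal_coupling_used: dict[str, float] = field(default_factory=dict)
    thal_diffusivity_used: dict[str, float] = field(default_factory=dict)

    @property
    def tha_smn_coupling(self) -> float:
        """Scalar somatomotor-thalamic coupling: strength + spread.

        This is the subject-level parameter the cognitive model consumes.
        """
        return self.thal_coupling_used["SMN"] + self.thal_diffusivity_used["SMN"]


@dataclass
class Cohort:
    """A generated cohort: subjects plus the shared thalamus geometry."""

    subjects: list[SyntheticSubject]
    thalamus: ThalamusGeometry
    spec: CohortSpec

    def phenotypes(self) -> pd.DataFrame:
        rows = [vars(s.record) for s in self.subjects]
        return pd.DataFrame(rows)

    def by_group(self, group: str) -> list[SyntheticSubject]:
        return [s for s in self.subjects if s.record.group == group]


def _simulate_motion(rng: np.random.Generator, n_t: int) -> np.ndarray:
    """Smoothed random-walk rigid-body parameters (3 transl. mm, 3 rot. rad)."""
    steps = rng.normal(0.0, 1.0, size=(n_t, 6))
    kernel = np.hanning(7)
    kernel /= kernel.sum()
    smooth = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, steps)
    walk = np.cumsum(smooth, axis=0)
    walk[:, :3] *= 0.02   # translations, mm
    walk[:, 3:] *= 0.0004  # rotations, rad
    return walk


def _generate_subject(
    spec: CohortSpec,
    group: str,
    subject_id: str,
    thalamus: ThalamusGeometry,
    rng: np.random.Generator,
    demo_rng: np.random.Generator,
) -> SyntheticSubject:
    n_t = spec.n_timepoints
    lam = spec.between_matrix(group)
    chol = np.linalg.cholesky(lam)
    latents = rng.standard_normal((n_t, N_NETWORKS)) @ chol.T

    # cortical parcels
    cortex = np.empty((n_t, spec.n_parcels))
    within = spec.within_coupling.get(group, {})
    for m, name in enumerate(NETWORKS):
        idx = np.flatnonzero(spec.partition == m)
        a = within.get(name, 0.0)
        noise = rng.standard_normal((n_t, idx.size))
        cortex[:, idx] = np.sqrt(a) * latents[:, [m]] + np.sqrt(1.0 - a) * noise

    # subject-level jitter of thalamic couplings: the strength c is scaled
    # multiplicatively, the diffusivity d shifted additively, by independent
    # draws. The subject's scalar "tha_SMN coupling" (strength + spread) is
    # what the cognitive model consumes.
    scale = float(np.clip(1.0 + spec.coupling_jitter_sd * rng.standard_normal(), 0.5, 1.5))
    d_shift = float(spec.diffusivity_spread * rng.standard_normal())
    c_group = spec.thal_coupling.get(group, _uniform(0.0))
    d_group = spec.thal_diffusivity.get(group, _uniform(0.0))
    c_used = {n: float(np.clip(c_group.get(n, 0.0) * scale, 0.0, 0.95)) for n in NETWORKS}
    d_used = {
        n: float(np.clip(d_group.get(n, 0.0) + d_shift, 0.0, 0.90)) if d_group.get(n, 0.0) > 0
        else 0.0
        for n in NETWORKS
    }

    # thalamic voxels
    rho = spec.thal_noise_shared
    eta = rng.standard_normal((n_t, N_NETWORKS))  # shared per-network noise
    V = thalamus.n_voxels
    thal = np.empty((n_t, V))
    bases = np.empty((n_t, N_NETWORKS))
    for m in range(N_NETWORKS):
        d = d_used[NETWORKS[m]]
        w = np.full(N_NETWORKS, np.sqrt(d / (N_NETWORKS - 1)))
        w[m] = np.sqrt(1.0 - d)
        base = latents @ w
        bases[:, m] = base / np.sqrt(w @ lam @ w)
    if spec.mirror_hemispheres:
        n_left = int((thalamus.hemisphere == 0).sum())
        eps_left = rng.standard_normal((n_t, n_left))
        eps = np.empty((n_t, V))
        eps[:, thalamus.hemisphere == 0] = eps_left
        eps[:, thalamus.hemisphere == 1] = eps_left  # mirrored draws
    else:
        eps = rng.standard_normal((n_t, V))
    for v in range(V):
        m = thalamus.true_labels[v]
        c = c_used[NETWORKS[m]]
        noise = np.sqrt(rho) * eta[:, m] + np.sqrt(1.0 - rho) * eps[:, v]
        thal[:, v] = np.sqrt(c) * bases[:, m] + np.sqrt(1.0 - c) * noise

    # nuisance regressors and framewise displacement
    motion6 = _simulate_motion(rng, n_t)
    fd = framewise_displacement(motion6)
    wm_csf = np.cumsum(rng.normal(0, 0.1, size=(n_t, 2)), axis=0)
    wm_csf += rng.normal(0, 1.0, size=(n_t, 2))
    wm_csf = (wm_csf - wm_csf.mean(0)) / wm_csf.std(0)
    nuisance = np.column_stack([friston24(motion6), wm_csf])

    # phenotype row
    demo = DEMOGRAPHICS[group]
    age = float(np.clip(demo_rng.normal(*demo["age"]), 18, 60))
    sex = "M" if demo_rng.random() < demo["male_frac"] else "F"
    education = float(np.clip(np.round(demo_rng.normal(*demo["education"])), 6, 19))
    intercept, slope, moca_sd = spec.moca_model.get(group, (27.0, 0.0, 1.5))
    lo, hi = _MOCA_RANGE[group]
    smn_coupling = c_used["SMN"] + d_used["SMN"]  # strength + spread
    moca = int(np.clip(np.round(
        intercept + slope * smn_coupling + moca_sd * demo_rng.standard_normal()
    ), lo, hi))
    record = SubjectRecord(subject_id, group, age, sex, education, moca)
    if group != "HC":
        record.onset_age = float(np.clip(demo_rng.normal(*demo["onset_age"]), 1, age - 0.5))
        record.duration = float(demo["duration_median"] * np.exp(demo_rng.normal(0, 0.6)))
        record.seizure_freq = float(np.round(
            demo["seizure_median"] * np.exp(demo_rng.normal(0, 1.0)), 2
        ))
        record.aed = "mono" if demo_rng.random() < demo["mono_frac"] else "poly"

    cortical_ts = ParcelTimeSeries(
        cortex, tr_seconds=spec.tr_seconds,
        region_names=[f"{NETWORKS[m]}_{i:03d}" for i, m in enumerate(spec.partition)],
    )
    return SyntheticSubject(
        record=record,
        cortical_ts=cortical_ts,
        thalamic_ts=thal,
        nuisance=nuisance,
        fd=fd,
        true_voxel_labels=thalamus.true_labels.copy(),
        thal_coupling_used=c_used,
        thal_diffusivity_used=d_used,
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort; deterministic given ``spec.seed``."""
    validate_spec(spec)
    thalamus = make_thalamus(spec.thal_grid)
    n_total = sum(spec.n_per_group.get(g, 0) for g in GROUPS)
    seeds = np.random.SeedSequence(spec.seed).spawn(2 * n_total)
    subjects: list[SyntheticSubject] = []
    i = 0
    for group in GROUPS:
        for j in range(spec.n_per_group.get(group, 0)):
            rng = np.random.default_rng(seeds[2 * i])
            demo_rng = np.random.default_rng(seeds[2 * i + 1])
            sid = f"sub-{group.replace('TLE-', '').lower()}{j + 1:03d}"
            subjects.append(_generate_subject(spec, group, sid, thalamus, rng, demo_rng))
            i += 1
    return Cohort(subjects, thalamus, spec)


# ---------------------------------------------------------------------------
# on-disk format

_FLOAT_FMT = "%.17g"  # lossless float round trip


def write_cohort(cohort: Cohort, out_dir: str | Path, overwrite: bool = False) -> Path:
    """Write a cohort as TSVs + NIfTI volumes + a provenance manifest."""
    import nibabel as nib

    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")
    out.mkdir(parents=True, exist_ok=True)

    for s in cohort.subjects:
        sid = s.record.subject_id
        header = "\t".join(s.cortical_ts.region_names)
        np.savetxt(out / f"{sid}_ts.tsv", s.cortical_ts.values, fmt=_FLOAT_FMT,
                   delimiter="\t", header=header, comments="")
        np.savetxt(out / f"{sid}_thal.tsv", s.thalamic_ts, fmt=_FLOAT_FMT, delimiter="\t")
        np.savetxt(out / f"{sid}_nuisance.tsv", s.nuisance, fmt=_FLOAT_FMT, delimiter="\t")
        np.savetxt(out / f"{sid}_fd.tsv", s.fd, fmt=_FLOAT_FMT, delimiter="\t")

    pheno = cohort.phenotypes()
    pheno.to_csv(out / "participants.tsv", sep="\t", index=False, na_rep="n/a")

    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    nib.save(nib.Nifti1Image(cohort.thalamus.prob_volume.astype(np.float32), affine),
             out / "thalamus_mask.nii.gz")
    nib.save(nib.Nifti1Image(cohort.thalamus.label_volume().astype(np.int16), affine),
             out / "true_labels.nii.gz")
    np.savetxt(out / "thal_voxel_coords.tsv", cohort.thalamus.voxel_coords,
               fmt="%d", delimiter="\t")

    manifest = {
        "package": "thalmod",
        "seed": cohort.spec.seed,
        "n_subjects": len(cohort.subjects),
        "spec": cohort.spec.to_dict(),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def read_cohort(in_dir: str | Path) -> Cohort:
    """Round-trip reader for :func:`write_cohort` output."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    spec = CohortSpec.from_dict(manifest["spec"])
    thalamus = make_thalamus(spec.thal_grid)
    pheno = pd.read_csv(in_dir / "participants.tsv", sep="\t", na_values=["n/a"])
    subjects = []
    for _, row in pheno.iterrows():
        sid = row["subject_id"]
        values = np.loadtxt(in_dir / f"{sid}_ts.tsv", delimiter="\t", skiprows=1)
        with open(in_dir / f"{sid}_ts.tsv") as fh:
            names = fh.readline().strip().split("\t")
        ts = ParcelTimeSeries(values, tr_seconds=spec.tr_seconds, region_names=names)
        thal = np.loadtxt(in_dir / f"{sid}_thal.tsv", delimiter="\t")
        nuis = np.loadtxt(in_dir / f"{sid}_nuisance.tsv", delimiter="\t")
        fd = np.loadtxt(in_dir / f"{sid}_fd.tsv", delimiter="\t")

        def opt(v):
            return None if pd.isna(v) else v

        record = SubjectRecord(
            subject_id=sid, group=row["group"], age=row["age"], sex=row["sex"],
            education=row["education"], moca=int(row["moca"]),
            onset_age=opt(row.get("onset_age")), duration=opt(row.get("duration")),
            seizure_freq=opt(row.get("seizure_freq")), aed=opt(row.get("aed")),
        )
        subjects.append(SyntheticSubject(
            record=record, cortical_ts=ts, thalamic_ts=thal, nuisance=nuis, fd=fd,
            true_voxel_labels=thalamus.true_labels.copy(),
        ))
    return Cohort(subjects, thalamus, spec)
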