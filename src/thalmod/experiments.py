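"""Planted-effect validation experiments on synthetic cohorts.

These experiments close the loop between the generator's ground truth and
the analysis stack: label-recovery of the winner-take-all parcellation, and
direction-of-effect recovery for the group contrasts. Each planted
manipulation is studied in isolation so a detected difference is
attributable to the intended mechanism:

* cortical experiment — patients differ from controls only in the
  ventral-attention/default-mode within-coupling deficit; read-outs are
  global modularity Q (AUC over the sparsity sweep) and the modular
  segregation index of the affected networks, both expected lower.
* thalamic experiment — patients differ only in the elevated and more
  diffuse somatomotor thalamic coupling (plus the lowered default-mode
  thalamic coupling); read-outs are tha_SMN participation coefficient and
  within-module degree AUCs, both expected higher, and the within-patient
  correlation between tha_SMN PC AUC and the MoCA score, expected positive
  because the cognitive model ties MoCA to the same subject-level coupling.

The experiments run on the generated series directly (the generator's
output is already stationary and artefact-free, so the temporal cleaning
stages would only add estimation noise); the end-to-end path including
preprocessing is exercised by the pipeline runner.
"""

from __future__ import annotations

import numpy as np

from .cohort import _uniform, default_cohort_spec, generate_cohort
from .connectome import DEFAULT_LEVELS, MetricCurve, pearson_fc, threshold_sweep
from .modular import modular_segregation_index, modularity_q
from .networks import NETWORK_INDEX
from .parcellation import parcellate_cohort, subdivision_timeseries
from .stats import metric_moca_correlation, student_t
from .thalamocortical import build_thalamocortical, hub_metrics


def recovery_experiment(
    seed: int,
    n_subjects: int = 20,
    thal_coupling: float = 0.5,
    n_timepoints: int = 300,
) -> float:
    """Fraction of planted voxel labels recovered by winner-take-all.

    Uses a homogeneous control cohort whose thalamic voxels couple purely to
    their own network latent (diffusivity 0) at the given strength.
    """
    spec = default_cohort_spec(seed=seed)
    spec.n_per_group = {"HC": n_subjects, "TLE-CN": 0, "TLE-CI": 0}
    spec.n_timepoints = n_timepoints
    spec.thal_coupling = {"HC": _uniform(thal_coupling)}
    spec.thal_diffusivity = {"HC": _uniform(0.0)}
    spec.coupling_jitter_sd = 0.0
    spec.diffusivity_spread = 0.0
    cohort = generate_cohort(spec)
    labels = parcellate_cohort(
        [s.cortical_ts for s in cohort.subjects],
        spec.partition,
        [s.thalamic_ts for s in cohort.subjects],
        cohort.thalamus.voxel_coords,
    )
    return float((labels.labels == cohort.thalamus.true_labels).mean())


def _q_auc_and_msi(conn, labels, levels=DEFAULT_LEVELS) -> tuple[float, float, float]:
    """Q AUC across the sweep plus weight-based MSI for VAN and DMN."""
    graphs = threshold_sweep(conn, levels)
    q_vals = np.array([modularity_q(g, labels) for g in graphs])
    q_auc = MetricCurve(np.asarray(levels, float), q_vals).auc
    msi_van = modular_segregation_index(conn, labels, NETWORK_INDEX["VAN"])
    msi_dmn = modular_segregation_index(conn, labels, NETWORK_INDEX["DMN"])
    return q_auc, msi_van, msi_dmn


def _contrast(ci_vals: list[float], hc_vals: list[float]) -> dict:
    res = student_t(ci_vals, hc_vals)
    return {
        "mean_hc": float(np.mean(hc_vals)),
        "mean_ci": float(np.mean(ci_vals)),
        "t": res.statistic,
        "p": res.p_value,
    }


def cortical_effect_run(
    seed: int,
    n_per_group: int = 25,
    n_timepoints: int = 300,
    levels: np.ndarray = DEFAULT_LEVELS,
) -> dict:
    """One seed of the cortical direction-of-effect study.

    Patients carry only the within-coupling deficit of the ventral-attention
    and default-mode networks (thalamic parameters cloned from controls).
    """
    spec = default_cohort_spec(seed=seed)
    spec.n_per_group = {"HC": n_per_group, "TLE-CN": 0, "TLE-CI": n_per_group}
    spec.n_timepoints = n_timepoints
    spec.thal_coupling["TLE-CI"] = dict(spec.thal_coupling["HC"])
    spec.thal_diffusivity["TLE-CI"] = dict(spec.thal_diffusivity["HC"])
    cohort = generate_cohort(spec)

    values: dict[str, np.ndarray] = {}
    for group in ("HC", "TLE-CI"):
        rows = [
            _q_auc_and_msi(pearson_fc(s.cortical_ts), spec.partition, levels)
            for s in cohort.by_group(group)
        ]
        values[group] = np.asarray(rows)
    return {
        key: _contrast(values["TLE-CI"][:, i].tolist(), values["HC"][:, i].tolist())
        for i, key in enumerate(("q_auc", "msi_van", "msi_dmn"))
    }


def thalamic_effect_run(
    seed: int,
    n_per_group: int = 25,
    n_timepoints: int = 300,
    levels: np.ndarray = DEFAULT_LEVELS,
) -> dict:
    """One seed of the thalamic direction-of-effect study.

    Patients carry only the thalamic-coupling manipulation (cortical
    parameters cloned from controls), so tha_SMN hub differences reflect
    the planted elevated/diffuse coupling. Also returns the within-patient
    correlation between tha_SMN PC AUC and MoCA.
    """
    spec = default_cohort_spec(seed=seed)
    spec.n_per_group = {"HC": n_per_group, "TLE-CN": 0, "TLE-CI": n_per_group}
    spec.n_timepoints = n_timepoints
    spec.within_coupling["TLE-CI"] = dict(spec.within_coupling["HC"])
    spec.between_coupling["TLE-CI"] = spec.between_coupling["HC"]
    cohort = generate_cohort(spec)

    label_map = parcellate_cohort(
        [s.cortical_ts for s in cohort.subjects], spec.partition,
        [s.thalamic_ts for s in cohort.subjects], cohort.thalamus.voxel_coords,
    )
    pc = {"HC": [], "TLE-CI": []}
    wmd = {"HC": [], "TLE-CI": []}
    moca_ci, pc_ci = [], []
    for s in cohort.subjects:
        subdiv, present = subdivision_timeseries(s.thalamic_ts, label_map)
        tc = build_thalamocortical(s.cortical_ts, subdiv, spec.partition, present)
        hubs = hub_metrics(tc, levels=levels, n_cortical=spec.n_parcels)
        pc[s.record.group].append(hubs.pc_curves["SMN"].auc)
        wmd[s.record.group].append(hubs.wmd_curves["SMN"].auc)
        if s.record.group == "TLE-CI":
            moca_ci.append(s.record.moca)
            pc_ci.append(hubs.pc_curves["SMN"].auc)
    corr = metric_moca_correlation(np.array(pc_ci), np.array(moca_ci))
    return {
        "pc_smn": _contrast(pc["TLE-CI"], pc["HC"]),
        "wmd_smn": _contrast(wmd["TLE-CI"], wmd["HC"]),
        "pc_moca": {"r": corr.statistic, "p": corr.p_value, "test": corr.test_name},
    }


#: Each planted effect with its expected direction: sign of (impaired − control).
EFFECT_DIRECTIONS = {
    "q_auc": -1,       # lower global modularity in patients
    "msi_van": -1,     # lower ventral-attention segregation
    "msi_dmn": -1,     # lower default-mode segregation
    "pc_smn": +1,      # higher somatomotor-thalamic participation
    "wmd_smn": +1,     # higher somatomotor-thalamic within-module degree
}

_CORTICAL_KEYS = ("q_auc", "msi_van", "msi_dmn")
_THALAMIC_KEYS = ("pc_smn", "wmd_smn")


def detection_rates(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_per_group: int = 25,
    n_timepoints: int = 300,
    alpha: float = 0.05,
) -> dict:
    """Fraction of seeds on which each planted effect is detected.

    An effect counts as detected when the two-sample test is significant at
    ``alpha`` *and* the group difference has the planted direction; the
    cognition link when the PC–MoCA correlation is positive and significant.
    """
    detected = {key: 0 for key in EFFECT_DIRECTIONS}
    detected["pc_moca"] = 0
    runs = []
    for i in range(n_seeds):
        seed_i = base_seed + 1000 * (i + 1)
        run = dict(cortical_effect_run(seed_i, n_per_group, n_timepoints))
        run.update(thalamic_effect_run(seed_i + 500, n_per_group, n_timepoints))
        runs.append(run)
        for key, direction in EFFECT_DIRECTIONS.items():
            diff = run[key]["mean_ci"] - run[key]["mean_hc"]
            if run[key]["p"] < alpha and np.sign(diff) == direction:
                detected[key] += 1
        if run["pc_moca"]["p"] < alpha and run["pc_moca"]["r"] > 0:
            detected["pc_moca"] += 1
    rates = {key: detected[key] / n_seeds for key in detected}
    return {"rates": rates, "runs": runs, "n_seeds": n_seeds}
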