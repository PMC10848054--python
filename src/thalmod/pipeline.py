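"""End-to-end pipeline orchestration with a single YAML config.

Stages: simulate → preprocess → connectome/modular → parcellate → hubs →
stats. Each stage writes its tables under the output root together with a
provenance block (config hash, seed, package version); re-running with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, CohortSpec, default_cohort_spec, generate_cohort, write_cohort
from .connectome import DEFAULT_LEVELS, pearson_fc
from .modular import modular_report
from .networks import NETWORKS
from .parcellation import parcellate_cohort, subdivision_timeseries
from .preprocess import MotionSummary, ParcelTimeSeries, motion_exclude, run_temporal_pipeline
from .stats import bonferroni, auto_two_sample, metric_moca_correlation, run_table1
from .thalamocortical import build_thalamocortical, hub_metrics, roi_network_fc

STAGES = ("simulate", "preprocess", "connectome", "parcellate", "hubs", "stats")
#: Stage dependencies: a stage requires every stage listed for it.
_REQUIRES = {
    "preprocess": ("simulate",),
    "connectome": ("preprocess",),
    "parcellate": ("preprocess",),
    "hubs": ("parcellate",),
    "stats": ("connectome", "hubs"),
}


@dataclass
class PipelineConfig:
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    cohort: CohortSpec = None  # type: ignore[assignment]
    levels: np.ndarray = field(default_factory=lambda: DEFAULT_LEVELS.copy())
    mask_threshold: float = 0.10
    bandpass: tuple[float, float] | None = (0.01, 0.08)
    seed: int = 0
    out_root: str = "pipeline_out"

    def __post_init__(self) -> None:
        if self.cohort is None:
            self.cohort = default_cohort_spec(seed=self.seed)
        self.levels = np.asarray(self.levels, dtype=float)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        if "stages" in raw:
            stages = {s: True for s in STAGES}
            stages.update({k: bool(v) for k, v in raw["stages"].items()})
            kwargs["stages"] = stages
        seed = int(raw.get("seed", 0))
        kwargs["seed"] = seed
        if "cohort" in raw:
            spec = default_cohort_spec(seed=seed)
            for key, value in raw["cohort"].items():
                if not hasattr(spec, key):
                    raise ValueError(f"unknown cohort field {key!r}")
                setattr(spec, key, value)
            spec.thal_grid = tuple(spec.thal_grid)
            if "n_parcels" in raw["cohort"] and "partition" not in raw["cohort"]:
                spec.partition = None
            spec.__post_init__()
            spec.seed = seed
            kwargs["cohort"] = spec
        if "levels" in raw:
            kwargs["levels"] = np.asarray(raw["levels"], dtype=float)
        if "mask_threshold" in raw:
            kwargs["mask_threshold"] = float(raw["mask_threshold"])
        if "bandpass" in raw:
            band = raw["bandpass"]
            kwargs["bandpass"] = None if band in (None, False) else (float(band[0]), float(band[1]))
        if "out_root" in raw:
            kwargs["out_root"] = str(raw["out_root"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "stages": dict(self.stages),
            "cohort": self.cohort.to_dict(),
            "levels": self.levels.tolist(),
            "mask_threshold": self.mask_threshold,
            "bandpass": list(self.bandpass) if self.bandpass else None,
            "seed": self.seed,
            "out_root": self.out_root,
        }

    def config_hash(self) -> str:
        payload = self.to_dict()
        payload.pop("out_root", None)  # hash covers the scientific config only
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """Schema and cross-field checks; returns a list of findings."""
    findings: list[str] = []
    levels = config.levels
    if levels.size == 0 or (np.diff(levels) <= 0).any():
        findings.append("sparsity levels must be non-empty and strictly increasing")
    if levels.size and (levels.min() <= 0 or levels.max() > 1):
        findings.append("sparsity levels must lie in (0, 1]")
    if not 0 <= config.mask_threshold < 1:
        findings.append("mask threshold must lie in [0, 1)")
    if config.bandpass is not None:
        low, high = config.bandpass
        nyquist = 0.5 / config.cohort.tr_seconds
        if not 0 < low < high:
            findings.append("band-pass needs 0 < low < high")
        elif high >= nyquist:
            findings.append(
                f"band-pass high cutoff {high} Hz violates Nyquist {nyquist} Hz "
                f"for TR={config.cohort.tr_seconds}s"
            )
    for stage, deps in _REQUIRES.items():
        if config.stages.get(stage, False):
            for dep in deps:
                if not config.stages.get(dep, False):
                    findings.append(f"stage '{stage}' requires stage '{dep}'")
    try:
        from .cohort import validate_spec

        validate_spec(config.cohort)
    except ValueError as err:
        findings.append(f"cohort spec: {err}")
    return findings


def _log(log_path: Path, **event) -> None:
    with log_path.open("a") as fh:
        fh.write(json.dumps(event, sort_keys=True) + "\n")
    print(" ".join(f"{k}={v}" for k, v in event.items()))


def run_pipeline(config: PipelineConfig, write_raw: bool = False) -> Path:
    """Run all enabled stages; returns the output root.

    Raises on invalid config before any compute. ``write_raw`` additionally
    writes the simulated cohort's per-subject TSVs (large) to disk.
    """
    findings = validate_config(config)
    if findings:
        raise ValueError("invalid pipeline config: " + "; ".join(findings))
    out = Path(config.out_root)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline_log.jsonl"
    log_path.write_text("")
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    cohort: Cohort | None = None
    if config.stages.get("simulate", False):
        cohort = generate_cohort(config.cohort)
        if write_raw:
            write_cohort(cohort, out / "cohort", overwrite=True)
        _log(log_path, stage="simulate", n_subjects=len(cohort.subjects))
    if cohort is None:
        raise ValueError("pipeline currently requires the simulate stage as data source")

    partition = config.cohort.partition
    spec = config.cohort

    # preprocess + motion exclusion
    kept = cohort.subjects
    if config.stages.get("preprocess", False):
        kept = []
        for s in cohort.subjects:
            motion = MotionSummary(
                max_translation_mm=float(np.abs(s.nuisance[:, :3]).max()),
                max_rotation_deg=float(np.degrees(np.abs(s.nuisance[:, 3:6]).max())),
                mean_fd_mm=float(s.fd.mean()),
            )
            if motion_exclude(motion):
                _log(log_path, stage="preprocess", subject=s.record.subject_id,
                     excluded="motion")
                continue
            steps = ("drop", "detrend", "bandpass", "regress") if config.bandpass else (
                "drop", "detrend", "regress")
            low, high = config.bandpass or (0.01, 0.08)
            clean_cort = run_temporal_pipeline(
                s.cortical_ts, s.nuisance, n_drop=0, low_hz=low, high_hz=high, steps=steps)
            thal_ts = ParcelTimeSeries(s.thalamic_ts, tr_seconds=spec.tr_seconds)
            clean_thal = run_temporal_pipeline(
                thal_ts, s.nuisance, n_drop=0, low_hz=low, high_hz=high, steps=steps)
            kept.append(replace(s, cortical_ts=clean_cort, thalamic_ts=clean_thal.values))
        _log(log_path, stage="preprocess", n_kept=len(kept))

    # cortical connectome + modular metrics
    modular_rows = []
    if config.stages.get("connectome", False):
        for s in kept:
            conn = pearson_fc(s.cortical_ts, node_partition=partition)
            report = modular_report(conn, partition, levels=config.levels)
            modular_rows.append(report.to_long_dataframe(s.record.subject_id))
        modular_df = pd.concat(modular_rows, ignore_index=True)
        modular_df.to_csv(out / "modular_metrics.tsv", sep="\t", index=False,
                          float_format="%.6g")
        _log(log_path, stage="connectome", n_subjects=len(kept))

    # thalamus parcellation
    label_map = None
    if config.stages.get("parcellate", False):
        label_map = parcellate_cohort(
            [s.cortical_ts for s in kept], partition,
            [s.thalamic_ts for s in kept], cohort.thalamus.voxel_coords,
        )
        counts = label_map.voxel_counts
        pd.DataFrame([counts]).to_csv(out / "thalamic_voxel_counts.tsv", sep="\t", index=False)
        recovery = float((label_map.labels == cohort.thalamus.true_labels).mean())
        _log(log_path, stage="parcellate", recovery=round(recovery, 4), **counts)

    # thalamocortical hub metrics + subdivision-network FC
    hub_rows, roi_rows = [], []
    if config.stages.get("hubs", False):
        assert label_map is not None
        for s in kept:
            subdiv, present = subdivision_timeseries(s.thalamic_ts, label_map)
            tc = build_thalamocortical(s.cortical_ts, subdiv, partition, present)
            hm = hub_metrics(tc, levels=config.levels, n_cortical=spec.n_parcels)
            hub_rows.append(hm.to_dataframe(s.record.subject_id))
            for m, name in enumerate(NETWORKS):
                if present[m]:
                    roi_rows.append(dict(
                        subject=s.record.subject_id, group=s.record.group,
                        node=f"tha_{name}",
                        fc=roi_network_fc(subdiv[:, m], s.cortical_ts, partition, m),
                    ))
        pd.concat(hub_rows, ignore_index=True).to_csv(
            out / "hub_metrics.tsv", sep="\t", index=False, float_format="%.6g")
        pd.DataFrame(roi_rows).to_csv(out / "roi_network_fc.tsv", sep="\t",
                                      index=False, float_format="%.6g")
        _log(log_path, stage="hubs", n_subjects=len(kept))

    # statistics
    summary: dict = {"provenance": provenance}
    if config.stages.get("stats", False):
        pheno = cohort.phenotypes()
        pheno = pheno[pheno.subject_id.isin([s.record.subject_id for s in kept])]
        table1 = run_table1(pheno)
        table1.to_csv(out / "table1_report.tsv", sep="\t", index=False, float_format="%.6g")

        hub_df = pd.concat(hub_rows, ignore_index=True)
        hub_auc = hub_df.drop_duplicates(["subject", "node"])[
            ["subject", "node", "pc_auc", "wmd_auc"]]
        hub_auc = hub_auc.merge(pheno[["subject_id", "group", "moca"]],
                                left_on="subject", right_on="subject_id")
        groups_present = [g for g in ("HC", "TLE-CN", "TLE-CI") if (pheno.group == g).any()]
        comparisons = []
        for metric in ("pc_auc", "wmd_auc"):
            results, meta = [], []
            for node in sorted(hub_auc.node.unique()):
                sub = hub_auc[hub_auc.node == node]
                for ga, gb in [(a, b) for i, a in enumerate(groups_present)
                               for b in groups_present[i + 1:]]:
                    res = auto_two_sample(sub[sub.group == ga][metric],
                                          sub[sub.group == gb][metric])
                    results.append(res)
                    meta.append((node, f"{ga}-vs-{gb}"))
            for res, (node, pair) in zip(bonferroni(results, family_id=metric), meta):
                comparisons.append(dict(metric=metric, node=node, comparison=pair,
                                        test=res.test_name, statistic=res.statistic,
                                        p=res.p_value, p_bonferroni=res.corrected_p))
        comp_df = pd.DataFrame(comparisons)
        comp_df.to_csv(out / "group_comparisons.tsv", sep="\t", index=False,
                       float_format="%.6g")

        correlations = []
        for group in groups_present:
            if group == "HC":
                continue
            sub = hub_auc[hub_auc.group == group]
            for metric in ("pc_auc", "wmd_auc"):
                for node in sorted(sub.node.unique()):
                    vals = sub[sub.node == node]
                    if len(vals) < 5 or vals[metric].std(ddof=1) == 0:
                        continue
                    res = metric_moca_correlation(vals[metric].to_numpy(),
                                                  vals["moca"].to_numpy())
                    correlations.append(dict(group=group, metric=metric, node=node,
                                             test=res.test_name, r=res.statistic,
                                             p=res.p_value))
        pd.DataFrame(correlations).to_csv(out / "correlations.tsv", sep="\t",
                                          index=False, float_format="%.6g")

        if modular_rows:
            modular_df = pd.concat(modular_rows, ignore_index=True)
            q_auc = modular_df[modular_df.metric == "Q"].drop_duplicates("subject")
            q_auc = q_auc.merge(pheno[["subject_id", "group"]],
                                left_on="subject", right_on="subject_id")
            summary["q_auc_by_group"] = {
                g: round(float(q_auc[q_auc.group == g].auc.mean()), 6)
                for g in groups_present
            }
        summary["n_by_group"] = {g: int((pheno.group == g).sum()) for g in groups_present}
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        _log(log_path, stage="stats", summary="summary.json")

    return out
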