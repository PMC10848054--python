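"""Shared configuration for the numbered analysis drivers.

The demo study: 10 subjects per group, 200 cortical parcels, 300-volume
scans (TR 2 s), the default planted effects. Raw per-subject data live
under scratch/ (regenerated on demand); every driver writes its summary
tables under results/.
"""

from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "demo_cohort"
RESULTS = ROOT / "results"
SEED = 0
N_PER_GROUP = 10
N_TIMEPOINTS = 300


def demo_spec():
    from thalmod.cohort import default_cohort_spec

    spec = default_cohort_spec(seed=SEED)
    spec.n_per_group = {g: N_PER_GROUP for g in ("HC", "TLE-CN", "TLE-CI")}
    spec.n_timepoints = N_TIMEPOINTS
    return spec


def load_clean_cohort():
    """Cohort with the temporal pipeline applied (cached in scratch)."""
    import pickle

    cache = SCRATCH / "clean_cohort.pkl"
    if cache.exists():
        with cache.open("rb") as fh:
            return pickle.load(fh)
    raise SystemExit("run analysis/02_preprocess.py first")


def save_clean_cohort(cohort):
    import pickle

    SCRATCH.mkdir(parents=True, exist_ok=True)
    with (SCRATCH / "clean_cohort.pkl").open("wb") as fh:
        pickle.dump(cohort, fh)


def save_table(df, name, index=False):
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    print(f"wrote {path.relative_to(ROOT)} ({len(df)} rows)")
    return path


def group_of(cohort):
    return np.array([s.record.group for s in cohort.subjects])
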