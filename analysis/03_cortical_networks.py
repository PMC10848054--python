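#!/usr/bin/env python
"""Cortical modular metrics across the sparsity sweep.

Per subject: 200x200 Pearson connectivity, binary graphs at sparsity
0.1–1.0, modularity Q curve (AUC), modular segregation index per network,
and intra-/inter-module edge-count AUCs. Writes the long-format AUC table
and prints the group contrast for the affected networks.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from thalmod.connectome import pearson_fc  # noqa: E402
from thalmod.modular import modular_report  # noqa: E402
from thalmod.stats import student_t  # noqa: E402


def main() -> None:
    cohort = common.load_clean_cohort()
    partition = cohort.spec.partition
    frames = []
    for s in cohort.subjects:
        conn = pearson_fc(s.cortical_ts, node_partition=partition)
        report = modular_report(conn, partition)
        df = report.to_long_dataframe(s.record.subject_id)
        df["group"] = s.record.group
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    auc = long.drop_duplicates(["subject", "metric", "module"])[
        ["subject", "group", "metric", "module", "auc"]]
    common.save_table(auc, "modular_auc.tsv")

    q = auc[auc.metric == "Q"]
    print("\nmodularity Q AUC by group:")
    print(q.groupby("group").auc.agg(["mean", "std"]).round(4).to_string())
    for module in ("VAN", "DMN"):
        msi = auc[(auc.metric == "MSI") & (auc.module == module)]
        hc = msi[msi.group == "HC"].auc
        for patient in ("TLE-CN", "TLE-CI"):
            pat = msi[msi.group == patient].auc
            res = student_t(pat, hc)
            print(f"MSI {module}: {patient} vs HC  t = {res.statistic:+.2f}  "
                  f"p = {res.p_value:.2g}")


if __name__ == "__main__":
    main()
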