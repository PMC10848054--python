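#!/usr/bin/env python
"""Statistical layer: phenotype battery, hub-metric group comparisons with
Bonferroni correction, and metric-cognition correlations in patients."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from thalmod.stats import (  # noqa: E402
    auto_two_sample,
    bonferroni,
    metric_moca_correlation,
    run_table1,
)


def main() -> None:
    cohort = common.load_clean_cohort()
    pheno = cohort.phenotypes()
    table1 = run_table1(pheno)
    common.save_table(table1, "table1.tsv")

    hub = pd.read_csv(common.RESULTS / "hub_auc.tsv", sep="\t")
    hub = hub.merge(pheno[["subject_id", "moca"]], left_on="subject",
                    right_on="subject_id")
    groups = ("HC", "TLE-CN", "TLE-CI")
    comparisons = []
    for metric in ("pc_auc", "wmd_auc"):
        results, meta = [], []
        for node in sorted(hub.node.unique()):
            sub = hub[hub.node == node]
            for i, ga in enumerate(groups):
                for gb in groups[i + 1:]:
                    res = auto_two_sample(sub[sub.group == ga][metric],
                                          sub[sub.group == gb][metric])
                    results.append(res)
                    meta.append((node, f"{ga}-vs-{gb}"))
        for res, (node, pair) in zip(bonferroni(results, family_id=metric), meta):
            comparisons.append(dict(metric=metric, node=node, comparison=pair,
                                    test=res.test_name, statistic=res.statistic,
                                    p=res.p_value, p_bonferroni=res.corrected_p))
    comp = pd.DataFrame(comparisons)
    common.save_table(comp, "group_comparisons.tsv")

    correlations = []
    for group in ("TLE-CN", "TLE-CI"):
        sub = hub[hub.group == group]
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
    corr = pd.DataFrame(correlations)
    common.save_table(corr, "correlations.tsv")

    sig = comp[comp.p_bonferroni < 0.05]
    print(f"\n{len(sig)} hub-metric contrasts survive Bonferroni correction:")
    if len(sig):
        print(sig[["metric", "node", "comparison", "statistic", "p_bonferroni"]]
              .to_string(index=False))
    smn = corr[(corr.group == "TLE-CI") & (corr.node == "tha_SMN")]
    print("\ntha_SMN metric-MoCA correlations in the impaired group:")
    print(smn[["metric", "test", "r", "p"]].to_string(index=False))


if __name__ == "__main__":
    main()
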