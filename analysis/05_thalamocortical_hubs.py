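#!/usr/bin/env python
"""Thalamic hub metrics on the 207-node thalamocortical network.

Per subject: subdivision mean series, 207x207 correlation matrix, two-step
thresholding across the sweep, participation coefficient and within-module
degree z-score per thalamic node (AUC-summarised), and the subdivision-to-
own-network functional connectivity. Writes both tables and prints the
tha_SMN group contrast.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from thalmod.networks import NETWORKS  # noqa: E402
from thalmod.parcellation import parcellate_cohort, subdivision_timeseries  # noqa: E402
from thalmod.stats import student_t  # noqa: E402
from thalmod.thalamocortical import (  # noqa: E402
    build_thalamocortical,
    hub_metrics,
    roi_network_fc,
)


def main() -> None:
    cohort = common.load_clean_cohort()
    partition = cohort.spec.partition
    label_map = parcellate_cohort(
        [s.cortical_ts for s in cohort.subjects], partition,
        [s.thalamic_ts for s in cohort.subjects], cohort.thalamus.voxel_coords,
    )
    hub_rows, roi_rows = [], []
    for s in cohort.subjects:
        subdiv, present = subdivision_timeseries(s.thalamic_ts, label_map)
        tc = build_thalamocortical(s.cortical_ts, subdiv, partition, present)
        hm = hub_metrics(tc, n_cortical=cohort.spec.n_parcels)
        for name in hm.networks:
            hub_rows.append(dict(
                subject=s.record.subject_id, group=s.record.group, node=f"tha_{name}",
                pc_auc=hm.pc_curves[name].auc, wmd_auc=hm.wmd_curves[name].auc))
        for m, name in enumerate(NETWORKS):
            if present[m]:
                roi_rows.append(dict(
                    subject=s.record.subject_id, group=s.record.group,
                    node=f"tha_{name}",
                    fc=roi_network_fc(subdiv[:, m], s.cortical_ts, partition, m)))

    hub = pd.DataFrame(hub_rows)
    roi = pd.DataFrame(roi_rows)
    common.save_table(hub, "hub_auc.tsv")
    common.save_table(roi, "roi_network_fc.tsv")

    smn = hub[hub.node == "tha_SMN"]
    hc = smn[smn.group == "HC"]
    ci = smn[smn.group == "TLE-CI"]
    for metric in ("pc_auc", "wmd_auc"):
        res = student_t(ci[metric], hc[metric])
        print(f"tha_SMN {metric}: impaired vs control  t = {res.statistic:+.2f}  "
              f"p = {res.p_value:.2g}")
    fc_smn = roi[roi.node == "tha_SMN"].groupby("group").fc.mean().round(3)
    print("\nmean tha_SMN-to-SMN functional connectivity by group:")
    print(fc_smn.to_string())


if __name__ == "__main__":
    main()
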