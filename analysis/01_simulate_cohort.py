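#!/usr/bin/env python
"""Simulate the 17 responder / 17 non-responder study cohort.

Writes the clinical table and a demographic summary (group means/SDs with the
pooled two-sample t per covariate and the Yates chi2 for sex) to results/,
and prints where the generated cohort lands relative to the target summaries.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tdcsfc.io import records_to_table
from tdcsfc.model_eval import two_sample_t_from_summary, yates_chi2
from tdcsfc.synthetic import SimConfig, CLINICAL_GROUP_STATS, make_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

cohort = make_cohort(17, 17, SimConfig(seed=0))
table = records_to_table([rec for rec, _ in cohort])
table.to_csv(OUT / "clinical_cohort.tsv", sep="\t", index=False)

resp = table[table.is_responder == 1]
nonresp = table[table.is_responder == 0]
rows = []
for col in CLINICAL_GROUP_STATS["responder"]:
    if col == "percent_improvement":
        continue
    m1, s1 = resp[col].mean(), resp[col].std(ddof=1)
    m2, s2 = nonresp[col].mean(), nonresp[col].std(ddof=1)
    rows.append(
        {
            "covariate": col,
            "responder_mean": round(m1, 2),
            "responder_sd": round(s1, 2),
            "nonresponder_mean": round(m2, 2),
            "nonresponder_sd": round(s2, 2),
            "pooled_t": round(two_sample_t_from_summary(m1, s1, 17, m2, s2, 17), 2),
        }
    )
summary = pd.DataFrame(rows)
sex_table = np.array(
    [
        [resp.sex.sum(), nonresp.sex.sum()],
        [(1 - resp.sex).sum(), (1 - nonresp.sex).sum()],
    ]
)
summary.to_csv(OUT / "demographic_summary.tsv", sep="\t", index=False)

print(f"cohort: {len(cohort)} subjects "
      f"({int(table.is_responder.sum())} responders)")
print(summary.to_string(index=False))
print(f"sex table {sex_table.tolist()}  chi2 = {yates_chi2(sex_table):.2f}")
print(f"wrote {OUT / 'clinical_cohort.tsv'} and {OUT / 'demographic_summary.tsv'}")
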