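#!/usr/bin/env python
"""Monte Carlo dose and hazard percentiles per age-gender stratum.

Propagates the pooled concentration model (zero-inflated lognormal fitted
to the printed survey totals: mean 0.04, SD 0.04 mg/kg, 89% detection,
truncated at 0.39) together with each stratum's intake and body-weight
lognormals through LADD = C x IR x AF / BW x ED/AT at 100,000 draws, and
screens the result against the EFSA reference dose of 0.36 ug/kg bw/day.
Output: results/group_exposure.csv
"""

import os

import pandas as pd

import dietpra as dp
from dietpra.synthetic import ConsumptionGroup

SEED = 1

os.makedirs("results", exist_ok=True)
(total,) = [t for t in dp.load_table1_summaries() if t.region == "Total"]
model = dp.from_summary(total)
groups = [
    ConsumptionGroup.from_row(row)
    for row in dp.load_table2_groups().itertuples(index=False)
]
params = dp.ExposureParams(rfd=0.36, iterations=100_000, seed=SEED)
summaries = dp.run_all_groups(model, groups, params)

df = pd.DataFrame(
    [
        (s.group, s.ladd_p50, s.ladd_p90, s.ladd_p95, s.hi_p50, s.hi_p90, s.hi_p95)
        for s in summaries
    ],
    columns=["group", "ladd_p50", "ladd_p90", "ladd_p95",
             "hi_p50", "hi_p90", "hi_p95"],
)
df.round(4).to_csv("results/group_exposure.csv", index=False)

adult_male = df[df.group == "19-65 years, male"].iloc[0]
print(
    f"adult males (19-65): P50 LADD {adult_male.ladd_p50:.3f} ug/kg bw/day; "
    f"HI P50/P90/P95 = {adult_male.hi_p50:.2f}/{adult_male.hi_p90:.2f}/"
    f"{adult_male.hi_p95:.2f}"
)
top = df.loc[df.ladd_p50.idxmax()]
print(f"highest median dose: {top.group} ({top.ladd_p50:.3f} ug/kg bw/day)")
over = df[df.hi_p95 > 1]
print(f"strata with P95 hazard index above 1: {len(over)} of {len(df)}")
print("wrote results/group_exposure.csv")
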