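# dietpra — probabilistic dietary cadmium risk assessment for rice

`dietpra` estimates the chronic health risk that rice consumers incur from
cadmium (Cd) contamination, for the Taiwanese population stratified into 14
age–gender groups and 17 rice-producing regions. It is aimed at food-safety
assessors who have contaminant *survey summaries* (per-region sample counts,
means, SDs, maxima, an overall detection rate) and *consumption statistics*
(per-stratum intake and body-weight means/SDs with observed ranges) rather
than raw microdata, and who want a reproducible, scriptable Monte Carlo
assessment instead of a spreadsheet add-in.

## Model

Exposure is quantified by the lifetime average daily dose

    LADD = (C × IR × AF) / BW × ED / AT        [µg/kg bw/day]

where C is the Cd concentration in rice (mg/kg fresh weight ≡ µg/g), IR the
daily rice intake (g/day), AF the absorbed fraction (1.0 — complete
absorption, a conservative screening assumption), BW body weight (kg) and
ED/AT the exposure duration over averaging time (1.0 — lifetime exposure
averaged over a lifetime). Non-carcinogenic risk is screened by the hazard
index HI = LADD / RfD with RfD = 0.36 µg/kg bw/day (the EFSA tolerable
weekly intake of 2.5 µg/kg bw divided by 7); HI > 1 flags potential concern.

Every exposure factor is a lognormal parameterized from its *arithmetic*
mean m and SD s by the method of moments, σ² = ln(1 + (s/m)²),
µ = ln m − σ²/2; intake distributions are truncated to their surveyed
ranges by inverse-CDF restriction. Concentrations are left-censored (11%
non-detects recorded as zero) and modelled as a zero-inflated lognormal
whose mixture moments match the survey mean/SD. Each simulation draws
100,000 independent (C, IR, BW) triples per stratum on a label-keyed RNG
substream and reports P50/P90/P95 of LADD and HI. Because the raw
1,581-sample survey is not public, a calibrated synthetic survey generator
reproduces the per-region summary structure so the whole pipeline is
testable end to end.

## Worked example

The numbered scripts under `analysis/` run the full study; each writes its
table under `results/`. For instance:

```sh
$ python analysis/03_group_exposure.py
adult males (19-65): P50 LADD 0.050 ug/kg bw/day; HI P50/P90/P95 = 0.14/0.66/0.99
highest median dose: 0-3 years, male (0.144 ug/kg bw/day)
strata with P95 hazard index above 1: 9 of 14
wrote results/group_exposure.csv
```

Read: the median adult male consumer ingests 0.050 µg Cd per kg body weight
per day from rice — 14% of the tolerable daily dose, no concern — but at
the 95th percentile of the joint concentration/consumption distribution the
hazard index approaches 1, and toddlers (highest intake per kg body weight)
carry the largest median dose. The regional driver ranks Yilan as the
riskiest production area and Taitung the safest:

```sh
$ python analysis/04_regional_hi.py
regional median hazard index (adult males), highest first:
  Yilan        0.374
  Taichung     0.331
  ...
  Taitung      0.067
```

The same computations are available as a CLI (`dietpra synth | summarize |
simulate | regional | run`) and as library calls:

```python
import dietpra as dp
from dietpra.synthetic import ConsumptionGroup

total, = [t for t in dp.load_table1_summaries() if t.region == "Total"]
model = dp.from_summary(total)                       # zero-inflated lognormal
groups = [ConsumptionGroup.from_row(r)
          for r in dp.load_table2_groups().itertuples(index=False)]
out = dp.run_all_groups(model, groups, dp.ExposureParams(seed=1))
```

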