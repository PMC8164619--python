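# Methods

## Dose model

The assessment propagates three stochastic exposure factors through the
lifetime-average-daily-dose equation

    LADD = (C × IR × AF) / BW × ED / AT,

with units chosen so no conversion constant appears: C in mg/kg fresh
weight (numerically µg/g), IR in g/day, BW in kg, giving LADD in µg/kg
bw/day. Risk is screened with the hazard index HI = LADD/RfD.

Deterministic factors and their defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| AF | 1.0 | fraction | complete absorption — a deliberately conservative screening choice; the ~6% gastrointestinal absorption reported for Cd is informational only |
| ED/AT | 1.0 | — | lifetime exposure averaged over a lifetime; any shorter window would scale all results by ED/AT |
| RfD | 0.36 | µg/kg bw/day | EFSA tolerable weekly intake 2.5 µg/kg bw ÷ 7, rounded to 2 decimals for display; the unrounded 0.35714… is retained internally, and the US EPA food/water reference doses are selectable alternatives |
| iterations | 100,000 | draws | median standard error ≈ 0.45% per stratum; doubling changes reported 2-decimal values only through rounding |

## Exposure-factor distributions

Intake and body weight per age–gender stratum, and the concentration of
detected samples, are known only through arithmetic mean m, SD s and
(for intake) an observed range. Each is modelled lognormal by the method
of moments:

    σ² = ln(1 + (s/m)²),   µ = ln m − σ²/2,

which reproduces m and s exactly in the untruncated model (unit-tested to
1e−12 and cross-checked by numerical integration of the fitted density).
Maximum-likelihood fitting is not an option without microdata. s = 0
degenerates cleanly to a point mass at m.

Intake ranges are enforced as hard truncation via the inverse CDF
restricted to [F(lower), F(upper)] — deterministic for a given generator
state and rejection-free. µ and σ are *not* re-calibrated after
truncation: no re-calibration procedure is identifiable from summary
moments, and the induced downward bias in the realized mean is small
(≲0.5% for the widest intake ranges) and is measured in the test suite
rather than hidden. An interval retaining less than 1e−12 probability
mass raises an infeasible-truncation error.

Concentration is left-censored: non-detects (11% of samples overall) are
recorded as exactly zero, and all survey moments include those zeros.
The model is therefore a zero-inflated lognormal — a point mass at zero
with weight p₀ = 1 − detection rate, mixed with a lognormal for detected
values. When built from a printed summary row, the positive part is
solved from the mixture moments (m_pos = mean/(1−p₀), second moment
scaled likewise) and truncated above at the printed maximum; if the
implied positive-part variance is non-positive the model degenerates to a
point mass. C, IR and BW are sampled independently: no correlation
structure is estimable from the available summaries, and none is assumed.

## Monte Carlo engine

Each stratum draws `iterations` independent triples, applies the dose
equation draw-wise and reports P50/P90/P95 by the linear-interpolation
(type-7) percentile rule — the estimator choice is immaterial beyond the
4th decimal at 10⁵ draws. HI percentiles are the unrounded LADD
percentiles divided by RfD (exact, since positive scaling commutes with
order statistics); tables display two decimals but all arithmetic uses
unrounded values, which resolves apparent rounding mismatches such as a
printed dose of 0.55 pairing with HI 1.54 rather than 0.55/0.36 rounded
twice.

Every stratum and region gets its own RNG substream derived from the
master seed and a BLAKE2b hash of its label, so results are bit-identical
across runs and independent of evaluation order, and permuting the input
rows cannot change any number.

A closed-form oracle guards the whole chain: with censoring and
truncation disabled, ln LADD is normal with mean µ_C + µ_IR − µ_BW and
variance σ_C² + σ_IR² + σ_BW², and the suite requires every simulated
percentile to sit within 3 Monte Carlo standard errors of the analytic
value.

## Synthetic survey generator

The sample-level concentration survey is not deposited, so the generator
emulates it from the per-region summaries: for each region it draws n
values from the moment-matched zero-inflated model, with three
calibration choices made once, up front:

- the non-detect count is fixed at n − round(n × detection rate) rather
  than Bernoulli-sampled, so the censoring fraction is exact by
  construction (per-region detection rates are not published; all regions
  use the overall 89%);
- detected values use stratified (Latin-hypercube) inverse-CDF sampling —
  one draw per equal-probability stratum in random order — so sample
  moments concentrate tightly around model moments even at the smallest
  regional n (32–210);
- draws above the printed regional maximum are clipped to it (not
  redrawn), which respects the observed max while costing far less mean
  than re-draw truncation; values are then rounded to 0.1 µg/kg, the
  resolution a laboratory table would report, and anything below the
  censoring threshold (default 0.002 mg/kg) is zeroed and flagged
  non-detect.

The residual mean bias is analytic, largest (≈−0.003 mg/kg) for the
region whose maximum is closest to its mean, and the generated survey
reproduces every printed regional mean within ±0.01 mg/kg, never exceeds
a printed maximum, and lands within 2 points of the 89% detection rate.
The nominal instrument quantification limit of 0.2 mg/kg is kept as
metadata only: it is incompatible with a 0.04 mg/kg survey mean at 89%
detection, so the working censoring threshold is configurable and
defaults to 0.002 mg/kg, at which the requested detection rate is
achievable. Survey years are assigned uniformly over 2010–2018; no
per-year trend is calibrated because per-region yearly moments are not
published.

What the generator does *not* emulate: spatial or soil-covariate
structure, temporal trends, repeated measurements, or any
concentration–consumption correlation. Tests passing on synthetic data
therefore validate the pipeline's statistical machinery, not the field
representativeness of any particular survey.

## Known limitations

- The distribution family originally fitted to the concentration data is
  not recoverable from published summaries; moment-fitted lognormals
  reproduce central percentiles (P50/P90) robustly but the P95 tail is
  family-sensitive, so upper-tail agreement with published tables is
  qualitative (strict monotonicity, 1/RfD scaling), not numeric.
- Two strata (females 16–18 and females 19–65) have median doses within
  ~0.3% of each other — far inside Monte Carlo resolution at 10⁵ draws —
  so "which stratum is lowest" is not a stable claim; both are ≈0.04
  µg/kg bw/day.
- Per-region hazard indices depend on region-specific fits that summary
  moments underdetermine; the regional *ranking* (Yilan highest, Taitung
  lowest) is robust, absolute regional values less so.
- Single-commodity assessment: no aggregate diet, no metal interactions,
  no carcinogenic slope factors, and a one-dimensional Monte Carlo that
  pools variability and uncertainty.
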