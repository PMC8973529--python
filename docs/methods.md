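# Methods

## Scoring model

PH-FRAT part 1 sums four ordinal items. Published descriptions of the
instrument give the total range (5–20), the item names, and that an
in-facility fall within the past 3 months scores 8 points on the
recent-falls item. The per-item point sets used here — recent falls
∈ {2, 4, 6, 8}, the other three items ∈ {1, 2, 3, 4} — are the unique
simple ordinal scheme consistent with those facts (minima sum to 5,
maxima to 20). Only the total matters downstream, so this reconstruction
does not affect any metric.

Classification is strict: predicted faller ⇔ score > cut-off. Risk groups
are low 5–11, medium 12–15, high 16–20; descriptions of the grouping
sometimes state a medium band of 12–16, but that overlaps the high band
and cannot partition the range, so the 12–15 boundary is used.

## Follow-up windows

The six-month horizon is implemented as **183 days** and is configurable
(`--window-days`); every downstream metric is insensitive to ±1 day at
the scales involved. A window ends at
`min(assessed_at + horizon, exit_at, study_end)`. Resident-days are
real-valued day differences (date-only records are read as midnight), not
inclusive day counts. A fall timestamped exactly at the assessment is
treated as occurring before its completion and excluded — the
conservative reading of "falls before the completion of the assessment
are excluded". Multiple same-day assessments are kept in file order as
distinct assessment indices; rows that duplicate an earlier row's
resident, timestamp *and* score are dropped with a logged warning. Falls
outside a resident's recorded stay are dropped with a warning. The study
window defaults to the data's own min/max timestamps.

## Metrics

With the extended table (TP, FP, FN, TN resident cells; per-predicted-row
fall totals F⁺, F⁻ and resident-day totals D⁺, D⁻):

* sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
  NPV = TN/(TN+FN), J = sens + spec − 1.
* sensitivity_ER = F⁺/(F⁺+F⁻), specificity_ER = D⁻/(D⁺+D⁻),
  J_ER = sens_ER + spec_ER − 1.

Note the ER metrics are *shares over all windows*: under equal window
lengths specificity_ER equals (TN+FN)/N, the predicted-negative fraction,
which differs from the standard specificity whenever the classifier errs.
Only sensitivity_ER collapses onto the standard sensitivity in the
one-fall-per-faller limit.

Zero-denominator metrics are returned as NaN with a `defined` flag, never
as 0.

**Intervals.** The method behind the published standard-metric intervals
is not restated there, so Wilson score intervals are used for the four
proportions (good small-sample behaviour, never escaping [0, 1]); Youden
under the standard method is reported without an interval. ER metrics and
the AUROC get a resident-level percentile bootstrap (default B = 1000,
seeded): residents are resampled with replacement and all their windows,
falls and days move together, respecting within-resident dependence of
recurrent falls. Because every cell of the extended table is additive
over residents at a fixed cut-off, replicates are computed as vectorised
sums of per-resident cell contributions. Replicates with an undefined
metric are dropped; more than 50% dropped is an error. BCa was not
implemented: the percentile interval is the simplest variant consistent
with the cluster resampling, and its coverage is verified by simulation
(see tests) to sit inside [90%, 99%] at nominal 95%.

**AUROC** is computed as the tie-corrected pairwise concordance
probability (scikit-learn's `roc_auc_score`), which equals the
trapezoidal area under the empirical ROC; the test suite checks both
identities against an exhaustive O(n²) pair count. The ROC table
evaluates every integer cut-off 4–20, so the curve always contains both
endpoints (sens 1/spec 0 at 4, sens 0/spec 1 at 20). The binary
observed-faller outcome at six months is the AUROC's response variable.
The optimal cut-off maximises Youden_ER (or Youden); ties break toward
the smallest cut-off, which maximises sensitivity among the optima.

**Incidence** uses the exact Poisson (Garwood) interval on the count,
`[χ²(0.025, 2k)/2, χ²(0.975, 2k+2)/2]`, scaled to per-1000 resident-days;
the lower bound is 0 at k = 0.

Rounding (percentages to 1 d.p., indices to 3 d.p.) happens only at the
reporting layer. One consequence: a Youden index computed from
full-precision cells can differ in the last digit from one computed from
already-rounded percentages (0.1487 → 0.149 vs 0.260 + 0.888 − 1 =
0.148); serialised reports always carry full precision.

## Synthetic cohort generator

The generator stands in for routinely collected aged-care data that
cannot be deposited. Per resident: type (respite fraction 0.186), sex
(65.9% female), age truncated-normal (mean 84.9, SD 7.7, min 65),
admission uniform over a 2014–2019 study window, stay lognormal (median
550 d permanent / 25 d respite), censoring at study end. Assessments: one
at entry, then lognormal gaps with median 43.8 d and log-SD 1.9 (chosen
so the gap IQR matches the observed 10.7–144 d). Components are drawn
from per-item categorical distributions concentrating the baseline total
around 13–14.

Falls are a point process with piecewise-constant intensity between
assessments:

    λ = min(base · frailty · exp(β (score − 14)), λ_max)

with base = 0.0070/day, β = 0.06 per point, lognormal mean-one frailty
(σ = 0.5), and a numerical ceiling λ_max = 1/day that never binds at
realistic settings. Two mechanisms couple score and risk:

* **Feedback:** a fall within the 90-day lookback before an assessment
  forces that assessment's recent-falls item to 8 points. This reproduces
  the upward drift of scores over repeated assessments and the rising
  sensitivity_ER at follow-up applications seen in routine data.
* **Latent-risk tilt:** each component's level probabilities are
  exponentially tilted by the resident's latent risk z (the same z that
  drives frailty), `p_i ∝ p_i · exp(0.2 z i)`, modelling assessors
  partially observing the resident's propensity to fall. Tilt 0 gives a
  near-null tool whose only signal is the transient causal term.

Under the defaults the simulated cohort shows a median total score of 14,
a crude rate of ≈7.5–7.6 falls/1000 resident-days and a baseline AUROC of
≈0.57–0.60 — the weak-discrimination regime the pipeline is designed to
measure. What the generator does **not** emulate: facility-level
clustering (all residents are exchangeable), intervention effects of
high-risk classification, seasonal or diurnal structure, injury severity,
and the long right tail of assessment counts (the observed median gap
between assessments comes out shorter than the sampled median because
long gaps are censored by discharge; observed medians of ≈3 assessments
and ≈27 d gaps correspond to target medians of 4 and 43.8 d). Passing
tests on simulated data therefore demonstrate correctness of the
pipeline's arithmetic and resampling, not external validity of any
particular metric value on real cohorts.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
shared fixtures use 400-resident cohorts; the bootstrap-coverage check
uses 200 replicates of 500 residents (B = 500) against a 20 000-resident
reference cohort; rate recovery uses 2000 residents; the acceptance
script's simulated block uses 2000 residents. The published headline
metrics need no simulation at all — they are exact arithmetic on printed
contingency tables.

## Known limitations

* The exact bootstrap variant used for the published ER intervals is not
  restated there; percentile with B = 1000 is this package's documented
  choice, so printed CI endpoints are not expected to reproduce exactly —
  only point estimates are.
* Respite readmission is not modelled: a respite resident's windows are
  truncated at their (single) discharge.
* The eligibility filter applies its three criteria sequentially, so the
  per-criterion exclusion counts depend on that order (age, then stay
  length, then assessment receipt).
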