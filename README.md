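# fratperf

Predictive-performance evaluation of the **Peninsula Health Falls Risk
Assessment Tool (PH-FRAT)** on longitudinal residential-aged-care data,
with the event-rate metric family for recurrent falls and a synthetic
cohort generator for fully reproducible pipelines.

PH-FRAT part 1 rates four fall risk factors — recent falls, medications,
psychological status, cognitive status — and sums them to an integer risk
score in [5, 20]; a score strictly above a cut-off (14 in the original
instrument) flags a resident as a likely faller. `fratperf` is aimed at
researchers and analysts who need to quantify how well such a score
predicts falls in routinely collected facility data, where falls are
recurrent events and follow-up is censored by discharge, death or study
end.

## What it computes

Each assessment (baseline or the k-th reapplication) anchors a follow-up
window `(t, min(t + 183 d, exit, study end)]`; falls at or before the
assessment are excluded. Cross-classifying predicted vs observed fallers,
while accumulating per-row fall counts and resident-days, gives an
extended 2×2 table from which two metric families follow:

* **Standard (resident-counting):** sensitivity TP/(TP+FN), specificity
  TN/(TN+FP), PPV, NPV, Youden's index J = sens + spec − 1, with Wilson
  95% intervals.
* **Event-rate (ER):** sensitivity_ER = (falls in predicted-faller
  windows)/(all falls), specificity_ER = (resident-days in predicted
  non-faller windows)/(all resident-days), Youden_ER — weighting by events
  and person-time so a resident with ten falls counts ten times. Intervals
  come from a resident-level (cluster) percentile bootstrap, which keeps
  each resident's windows and falls together.

Also: tie-corrected AUROC over the integer score range (equal to the
trapezoidal area under the empirical ROC), Youden/Youden_ER-optimal
cut-off search, crude incidence per 1000 resident-days with exact Poisson
(Garwood) intervals, permanent/respite subgroup analysis, and performance
at the 2nd–5th reapplication of the tool.

## Worked example

```python
from fratperf import SimulationConfig, simulate_cohort, evaluate

cfg = SimulationConfig(n_residents=1000)          # study-shaped defaults
residents, assessments, falls = simulate_cohort(cfg, seed=20140701)
report = evaluate(residents, assessments, falls, cutoffs=(14, 10),
                  n_boot=500, seed=20140701)

m = report.metrics["14"]
print(f"AUROC          : {report.auroc['estimate']:.2f}")
print(f"sensitivity    : {100*m['sensitivity']['estimate']:.1f}%")
print(f"sensitivity_ER : {100*m['sensitivity_er']['estimate']:.1f}%")
```

prints

```
windows evaluated : 991
AUROC             : 0.59
sensitivity       : 44.0%
specificity       : 68.2%
sensitivity_ER    : 51.5% (95% CI 46.9-56.9)
specificity_ER    : 61.9% (95% CI 58.8-65.1)
incidence         : 7.7 falls/1000 resident-days
```

Reading: at cut-off 14 the simulated tool catches 44% of residents who go
on to fall within six months of their baseline assessment, but 51.5% of
the *falls* occur in flagged residents (sensitivity_ER > sensitivity
because frequent fallers score higher); an AUROC of 0.59 is weak
discrimination. The same pipeline runs on real CSV exports via
`fratperf.io.read_residents/read_assessments/read_falls`.

The same analysis is available from the shell:

```bash
fratperf simulate --n-residents 1000 --seed 20140701 --out-dir data/
fratperf evaluate --residents data/residents.csv \
    --assessments data/assessments.csv --falls data/falls.csv \
    --cutoff 14 --cutoff 10 --bootstrap 500 --seed 20140701 --out results/
fratperf roc --residents data/residents.csv \
    --assessments data/assessments.csv --falls data/falls.csv
```

`evaluate` writes `results.json` (full precision, round-trippable via
`EvaluationReport.from_json`, which re-derives every metric from the
stored tables as a consistency check), `table2.csv` / `table3.csv` /
`fig3.csv` / `roc.csv` (tidy: one row per metric with `estimate`,
`ci_low`, `ci_high`, `ci_method`; `roc.csv` has one row per cut-off 4–20)
and `report.md`.

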