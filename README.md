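# riskaudit

Reliability and fairness audits of binary clinical risk models, validated
against clinician-generated surrogate outcome labels.

Deployed risk models — for example 12-month mortality models used to
prioritize patients for advance care planning — are rarely re-validated at
the site that uses them. `riskaudit` implements a complete audit procedure
for teams who want to do that with modest effort: gather clinician answers
to the *surprise question* ("Would you be surprised if this patient passed
away in Y years?", where "No" is the positive label), link them with model
scores and demographics, and quantify model performance and calibration
overall and across intersectional demographic subgroups.

## What it computes

Given an audit cohort of n records with binary labels, model probabilities
s_i and flags (s_i ≥ τ):

- **Performance** — sensitivity, specificity, PPV, accuracy and flag rate
  from the 2×2 table, each reported as a fraction (numerator/denominator)
  with a 95% CI from the **empirical (difference-method) bootstrap**: with
  B = 1,000 resamples, CI = [θ̂ − q₀.₉₇₅(θ\* − θ̂), θ̂ − q₀.₀₂₅(θ\* − θ̂)],
  null replicates excluded. Bounds may fall outside [0, 1].
- **Prevalence** — positive-label fraction with the exact
  **Clopper–Pearson** binomial interval.
- **Calibration** — the **O/E ratio**: observed events O = Σ labels over
  expected events E = Σ s_i, with a delta-method CI on the log scale,
  SE(ln O/E) = √((1 − φ)/O), φ = O/n (undefined when O = 0); plus
  score-quintile calibration curves.
- **Subgroup audit** — all of the above for every observed subgroup by sex,
  age decade (a, a+10], ethnicity×race, and ethnicity×race×sex. A subgroup
  is flagged when its CI and the overall CI are disjoint (prevalence in
  either direction; performance only when lower; O/E only when higher), and
  marked *inconclusive* when the metric's denominator is below 10.
- **Sample-size planning** — the minimum n whose implied O/E CI width meets
  a target: n = ⌈(1 − φ)/(φ·SE²)⌉ with SE = asinh(w/2)/z for width w about
  O/E = 1. For a 95% CI of [0.74, 1.34]: n = 176 at φ = 0.20, 66 at 0.40,
  19 at 0.70.
- **Class-balance sensitivity analysis** — random oversampling of the
  minority class, which leaves sensitivity/specificity unchanged (exact
  under integer duplication) but shifts PPV with prevalence.

A synthetic-cohort generator (`riskaudit.simulate`) emits the three input
tables with configurable per-subgroup prevalence and O/E miscalibration, so
the whole pipeline — including detection of a deliberately miscalibrated
stratum — is testable without any clinical data.

## Worked example

Reconstruct a 338-record primary-care cohort from its printed 2×2 table
(tp=25, fp=5, fn=43, tn=265) and expected-event total E=16.4, and audit it:

```python
from riskaudit import AuditConfig, fixture_from_counts, run_audit, significant_results_view

cohort = fixture_from_counts(tp=25, fp=5, fn=43, tn=265, e_target=16.4, threshold=0.15)
report = run_audit(cohort, AuditConfig(threshold=0.15))
print(significant_results_view(report).iloc[0].to_string())
```

```
Group                                          Overall
Sample Size                                        338
Prevalence (Fraction)                     0.2 (68/338)
Prevalence [95% CI]                       [0.16, 0.25]
Sensitivity (Fraction)                    0.37 (25/68)
Sensitivity [95% CI]                      [0.24, 0.49]
Specificity (Fraction)                  0.98 (265/270)
Specificity [95% CI]                       [0.97, 1.0]
Positive Predictive Value (Fraction)      0.83 (25/30)
Positive Predictive Value [95% CI]        [0.71, 0.98]
O/E (Fraction)                           4.1 (68/16.4)
O/E [95% CI]                                [3.4, 5.1]
```

Reading: of 338 labeled records, 68 (20%) carried a positive surprise-question
label; the model flagged 30, of which 25 were true positives, so it found
only 37% of the patients clinicians worried about, but 83% of its flags were
confirmed. O/E = 4.1 means clinicians identified four times as many events
as the model's probabilities predict — the model substantially
under-predicts risk relative to clinician judgment.

## Command line

```sh
riskaudit sample-size --prevalence 0.2           # -> n = 176, CI [0.74, 1.34]
riskaudit simulate --n 400 --seed 5 --out sim/   # synthetic input tables
riskaudit run --labels labels.csv --predictions predictions.csv \
    --demographics demographics.csv --config audit.yaml --out report/
```

`riskaudit run` writes `report.md`, `report.json`, `metrics.csv`,
`subgroups.csv`, `calibration_bins.csv` and an attrition log.

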