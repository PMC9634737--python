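# Methods

This note documents the statistical procedures implemented in `riskaudit`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish.

## Labels, linkage and the unit of analysis

The surrogate outcome is a clinician's answer to the surprise question
("Would you be surprised if this patient passed away in Y years?"). "No"
means the clinician would *not* be surprised, i.e. the patient is judged at
high risk: it maps to label 1. Answer matching is case-insensitive after
whitespace stripping, and only literal yes/no answers are accepted; anything
else ("Maybe", "TRANSFERRED", "Y/N", "DECEASED", …) is rejected with the
offending text recorded, so the rejected count is auditable.

The unit of analysis is the *label record*, not the patient. Patients
re-hospitalized during the labeling window legitimately appear multiple
times, and nothing deduplicates them; the bootstrap resamples records for
the same reason. Labels from different clinicians for the same patient are
likewise all kept — there is no defensible reconciliation rule without
knowing clinician identity semantics, and keeping all is the transparent
choice.

Two prediction-selection policies are supported: `most_recent_on_or_before`
(daily-scored models: the latest score dated on or before the label) and
`snapshot` (a single fixed-date extract per patient; several rows per
patient is an input error rather than a silent choice). Every label that
fails to link — no eligible prediction, or no demographics row — increments
a named attrition counter; `final + no_prediction + no_demographics =
labels_in` is an enforced invariant.

Age is completed years at the label date by calendar (month/day)
comparison — never day-count division by 365.25 — and decade bins are
half-open below, closed above: age 80 belongs to (70, 80]. Demographic
vocabularies are fixed (OMB-style sex, ethnicity and race levels); missing
values become "Unknown" and are *never* imputed. Unknown levels are kept in
the cohort and the overall row, but subgroups containing an Unknown level
are omitted from the subgroup axes by default (`include_unknown=True`
restores them), since a level that mixes refusals, data errors and true
unknowns does not support a disparity claim.

## Performance metrics and intervals

Fraction metrics (sensitivity, specificity, PPV, accuracy, flag rate,
prevalence) always carry their numerator and denominator. A zero
denominator makes the metric UNDEFINED — a first-class value (NaN) that
propagates to the report as `nan (0/0)` with an `N/A` interval, never an
exception, because those cells are informative in small subgroups.

Prevalence gets the exact Clopper–Pearson interval (beta quantiles; closed
forms at x = 0 and x = n), which is conservative by construction:
empirical coverage in tests is at or above the nominal level.

Performance metrics get the empirical (difference/basic) bootstrap:
B = 1,000 record-level resamples at the original size; differences
d_b = θ*_b − θ̂; CI = [θ̂ − q_{1−α/2}(d), θ̂ − q_{α/2}(d)] using the
inclusive linear-interpolation percentile on the sorted differences (the
convention is stated nowhere authoritative; this is numpy's default and is
frozen by the seeded tests). Replicates where the statistic is undefined
are excluded from the percentiles and reported as `n_null`, so extreme
subgroup intervals stay interpretable. Consequences worth knowing:

- bounds can fall outside [0, 1] (kept as-is; they are part of the method);
- a size-1 subgroup has a degenerate zero-width interval;
- subgroup CIs resample *within* the subgroup, around the subgroup's own
  point estimate — the degenerate printed intervals this produces are the
  reason small-n results are additionally gated by the inconclusive rule.

All metrics for one group are evaluated on one shared set of resamples
(the whole 2×2 table is recomputed per replicate), vectorized across
replicates; the generic per-statistic path draws the identical index
stream, and a test asserts the two paths agree exactly. Per-subgroup seeds
are spawned deterministically from the configured seed, so a seeded audit
is byte-reproducible regardless of subgroup count or order.

AUROC is reported for completeness (rank concordance, ties = 1/2, via
scikit-learn, cross-checked against a brute-force pairwise oracle in
tests); it carries no interval.

## Calibration

O = number of positive labels, E = sum of model output probabilities
(raw scores, not flags). O/E > 1 means the model under-predicts events
relative to clinicians. The delta-method interval is built on the log
scale: SE(ln O/E) = sqrt((1 − φ)/O) with φ = O/n, bounds
(O/E)·exp(∓z·SE). It follows that the interval is log-symmetric
(ci_low·ci_high = ratio²), contains the point estimate, is undefined at
O = 0, and collapses to zero width at φ = 1. When E = 0 with O > 0 the
ratio is reported as `inf` with an `N/A` interval; such a group can never
be flagged for higher O/E because the rule below requires both intervals
to be defined.

Calibration curves bin records by score quantiles (quintiles by default).
Duplicate quantile edges — common with heavily tied scores — are merged, so
fewer than K bins may be returned rather than empty ones; fewer records
than bins degrades to a single bin with a warning. Conservation invariants
(Σ n_bin = n, Σ n_bin·observed = O, Σ n_bin·predicted = E) are property-
tested.

## Significance and the inconclusive rule

Subgroup-vs-overall comparison uses CI disjointness, exactly as an audit
table reader would: two intervals are "significantly different" when they
do not overlap (touching endpoints overlap). This is a conservative
screening heuristic, not a two-sample test — it under-flags relative to a
formal test, and the subgroup interval is not independent of the overall
interval it is compared with. Direction follows reporting conventions:
prevalence differences are surfaced in both directions (label-consistency
check), performance only when *lower*, O/E only when *higher*.

Any flagged metric whose defining denominator (positives for sensitivity,
negatives for specificity, flagged count for PPV, subgroup size for
prevalence and O/E) is below `min_informative_n` (default 10) is marked
inconclusive. Inconclusive rows are annotated, never suppressed: hiding
small subgroups is how underrepresented groups get ignored.

## Sample-size planning

Planning inverts the delta-method interval. For a target width w of the
CI about an assumed O/E of 1, solve 2·sinh(z·SE) = w for SE, then
n = ⌈(1 − φ)/(φ·SE²)⌉. The ceiling guarantees minimality: the implied
width at n − 1 exceeds the target (property-tested). With the default
target (95% CI [0.74, 1.34], width 0.6) this gives n = 176, 66, 44 and 19
at φ = 0.20, 0.40, 0.50 and 0.70. Whether one targets the width or the
bounds is immaterial at assumed O/E = 1, where the two coincide; for
other assumed ratios the width equation generalizes to
2·oe·sinh(z·SE) = w. required_n is non-increasing in φ: rarer outcomes
need more records because O drives the variance.

## Class-balance analysis

`rebalance_cohort` performs random oversampling of the minority label
class to exact 50/50: each minority record is duplicated ⌊r⌋ extra times
plus a seeded random remainder subset. Duplication within a label class
cannot change sensitivity or specificity when the ratio is an integer
(and changes them only by the remainder subset otherwise), while PPV moves
with prevalence — the analysis exists to demonstrate exactly that
prevalence-dependence, not to produce better estimates; oversampled
cohorts are deliberately miscalibrated.

## Synthetic cohorts: what they emulate and what they do not

The generator draws demographics from a configurable mixture (defaults
approximate a large US academic health system's adult mix; marginals are
independent, which real populations are not), labels from per-subgroup
Bernoulli prevalences (default n = 338 at 20% prevalence, a primary-care-
sized validation), and scores from class-conditional Beta distributions.
Default betas — Beta(3, 3) for positives, Beta(1.5, 4) for negatives —
give realistic score overlap (AUROC ≈ 0.81, asserted in tests), in the
range reported for deployed mortality models; sharper separation would
make every downstream detection test too easy.

Miscalibration is injected multiplicatively: within each O/E stratum all
scores are rescaled so the stratum's score sum equals its realized O
divided by the target O/E, then clipped at 1. Using realized rather than
expected O makes the generated stratum's O/E exact, which is the sharper
ground truth for parameter-recovery tests; a target unreachable after
clipping raises an error naming the stratum instead of silently
truncating. Because rescaling is uniform within a stratum it changes E but
not the score ranking, so injected miscalibration leaves AUROC untouched —
a deliberate property (calibration and discrimination are separable) and
also a limitation: the generator cannot express score-dependent
(slope-type) miscalibration, only intercept-type.

`fixture_from_counts` reconstructs a linked cohort from a printed 2×2
table plus an expected-event total using two score levels (flagged records
at or above the threshold, unflagged below, solved so scores sum exactly
to E). It reproduces any table-level metric and O/E exactly, but its
two-point score distribution makes calibration curves collapse to one or
two bins — it exercises metrics, not curves.

Passing tests on these cohorts show the procedure is correct and that
effects of the injected size are detectable at the simulated n; they say
nothing about EHR data quality, demographic misclassification, or
informative attrition, which in real audits are the dominant threats.

## Numerical conventions

- CI level 0.95 everywhere by default; z = Φ⁻¹(0.975) ≈ 1.959964 exact,
  never 1.96.
- Reported tables round half-up: metrics and CP bounds to 2 decimals, O/E
  and its CI to 1; trailing zeros render as printed audit tables do
  ("0.2", "1.0"). Full precision is retained internally and in the JSON/CSV
  outputs; rounding is presentation-only.
- Default bootstrap seed 20220912; all randomness flows from explicit
  seeds and per-subgroup streams are spawned deterministically.
- Problem sizes in the test suite (e.g. n = 5000 cohorts, 20-seed
  parameter recovery, B = 10⁵ for the exhaustive-oracle comparison) were
  chosen as the smallest sizes at which the tested effects are clearly
  resolved.

## Known limitations

- The CI-overlap rule is conservative and informal; no multiplicity
  correction is applied across the many subgroups examined.
- Record-level resampling ignores clustering by clinician and by patient
  (repeat encounters); a cluster bootstrap is out of scope.
- The surprise question is a surrogate: the audit measures concordance
  with clinician judgment, not with mortality.
- BCa/studentized bootstraps, smoothed calibration curves and model
  recalibration are out of scope.
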