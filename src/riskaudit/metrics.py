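"""Confusion-matrix metrics, prevalence, and exact binomial intervals.

All fraction metrics carry their numerator and denominator so that small
samples stay interpretable; a metric whose denominator is zero is UNDEFINED
(NaN), a first-class value that propagates through reporting as ``nan (0/0)``
rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

METRIC_NAMES = (
    "prevalence",
    "sensitivity",
    "specificity",
    "ppv",
    "accuracy",
    "auroc",
    "flag_rate",
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    @property
    def flagged(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricEstimate:
    """A named fraction metric with CI and definedness status.

    ``value`` is ``numerator / denominator`` when the denominator is
    positive and NaN (UNDEFINED) otherwise.  Bootstrap CI bounds may fall
    outside [0, 1]; Clopper–Pearson bounds never do.
    """

    name: str
    value: float
    numerator: int | None = None
    denominator: int | None = None
    ci_low: float = math.nan
    ci_high: float = math.nan
    ci_method: str = "none"

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)

    @property
    def ci_defined(self) -> bool:
        return not (math.isnan(self.ci_low) or math.isnan(self.ci_high))

    def with_ci(self, ci_low: float, ci_high: float, ci_method: str) -> "MetricEstimate":
        return replace(self, ci_low=ci_low, ci_high=ci_high, ci_method=ci_method)


def _fraction(name: str, num: int, den: int) -> MetricEstimate:
    value = num / den if den > 0 else math.nan
    return MetricEstimate(name=name, value=value, numerator=int(num), denominator=int(den))


def confusion_counts(labels, scores, threshold: float) -> ConfusionCounts:
    """Tally the 2x2 table of binary labels against ``score >= threshold``."""
    labels = np.asarray(labels, dtype=int)
    flags = np.asarray(scores, dtype=float) >= threshold
    return confusion_from_flags(labels, flags)


def confusion_from_flags(labels, flags) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=bool)
    flags = np.asarray(flags, dtype=bool)
    if labels.shape != flags.shape:
        raise ValueError("labels and flags must have the same length")
    return ConfusionCounts(
        tp=int(np.sum(labels & flags)),
        fp=int(np.sum(~labels & flags)),
        fn=int(np.sum(labels & ~flags)),
        tn=int(np.sum(~labels & ~flags)),
    )


def metric_from_counts(name: str, counts: ConfusionCounts) -> MetricEstimate:
    """A single fraction metric from a 2x2 table, without a CI.

    sensitivity = tp/(tp+fn); specificity = tn/(tn+fp); ppv = tp/(tp+fp);
    accuracy = (tp+tn)/n; flag_rate = (tp+fp)/n; prevalence = (tp+fn)/n.
    """
    c = counts
    if name == "sensitivity":
        return _fraction(name, c.tp, c.positives)
    if name == "specificity":
        return _fraction(name, c.tn, c.negatives)
    if name == "ppv":
        return _fraction(name, c.tp, c.flagged)
    if name == "accuracy":
        return _fraction(name, c.tp + c.tn, c.n)
    if name == "flag_rate":
        return _fraction(name, c.flagged, c.n)
    if name == "prevalence":
        return _fraction(name, c.positives, c.n)
    raise ValueError(f"unknown metric name: {name!r}")


def prevalence_cp_ci(x: int, n: int, level: float = 0.95) -> MetricEstimate:
    """Exact (Clopper–Pearson) two-sided binomial interval for ``x/n``.

    The lower bound is exactly 0 when ``x = 0`` and the upper bound exactly
    1 when ``x = n``.  With ``n = 0`` the estimate is UNDEFINED.
    """
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if n == 0:
        return MetricEstimate(name="prevalence", value=math.nan, numerator=0, denominator=0)
    low, high = proportion_confint(x, n, alpha=1 - level, method="beta")
    return MetricEstimate(
        name="prevalence",
        value=x / n,
        numerator=int(x),
        denominator=int(n),
        ci_low=float(low),
        ci_high=float(high),
        ci_method="clopper_pearson",
    )


def auroc(scores, labels) -> MetricEstimate:
    """Rank-based concordance probability (ties count one half).

    UNDEFINED unless both a positive and a negative label are present.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        value = math.nan
    else:
        value = float(roc_auc_score(labels, scores))
    return MetricEstimate(name="auroc", value=value)
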