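"""Calibration: O/E ratio with delta-method CI and binned calibration curves.

O is the count of positive surrogate labels; E is the sum of the model's
output probabilities ("expected events").  O/E > 1 means the model
under-predicts events relative to clinicians.  The confidence interval is
built on the log scale with SE(ln O/E) = sqrt((1 - phi)/O) where
phi = O/n, and is undefined when O = 0 (O sits in the denominator of the
standard error).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass(frozen=True)
class OEResult:
    """Observed events, expected events, their ratio and delta-method CI."""

    observed: int
    expected: float
    n: int
    ratio: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    level: float = 0.95

    @property
    def ci_defined(self) -> bool:
        return not (math.isnan(self.ci_low) or math.isnan(self.ci_high))


@dataclass(frozen=True)
class CalibrationBin:
    index: int
    n: int
    mean_predicted: float
    observed_fraction: float


def oe_delta_ci(
    observed: int, expected: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided delta-method CI for O/E on the log scale.

    Bounds are ``(O/E) * exp(-+ z * SE)`` with ``SE = sqrt((1 - O/n)/O)``,
    hence log-symmetric: ``ci_low * ci_high = ratio**2``.  Undefined (NaN
    bounds) when ``O = 0`` or ``E = 0``.
    """
    if n < observed:
        raise ValueError(f"n={n} smaller than observed={observed}")
    if observed == 0 or expected <= 0:
        return (math.nan, math.nan)
    phi = observed / n
    se = math.sqrt((1 - phi) / observed)
    z = norm.ppf(0.5 + level / 2)
    ratio = observed / expected
    return (ratio * math.exp(-z * se), ratio * math.exp(z * se))


def oe_ratio(labels, scores, level: float = 0.95) -> OEResult:
    """O/E for a set of records, with its delta-method CI.

    ``ratio`` is ``inf`` when E = 0 with O > 0 (rendered "inf" in reports)
    and NaN when both are zero.  The CI is undefined whenever O = 0 or
    E = 0.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ValueError("records are empty")
    observed = int(labels.sum())
    expected = float(scores.sum())
    if expected > 0:
        ratio = observed / expected
    else:
        ratio = math.inf if observed > 0 else math.nan
    low, high = oe_delta_ci(observed, expected, labels.size, level=level)
    return OEResult(
        observed=observed,
        expected=expected,
        n=int(labels.size),
        ratio=ratio,
        ci_low=low,
        ci_high=high,
        level=level,
    )


def calibration_curve(labels, scores, k: int = 5) -> list[CalibrationBin]:
    """Score-quantile calibration bins (quintiles by default).

    Records are partitioned by score quantile boundaries into at most ``k``
    bins; duplicate boundaries (heavily tied scores) are merged, so fewer
    bins may be returned.  Per bin the mean predicted risk and the observed
    positive fraction are reported; bin sizes sum to n, observed events to
    O and predicted sums to E.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ValueError("records are empty")
    if labels.size < k:
        warnings.warn(
            f"fewer records ({labels.size}) than bins ({k}); using a single bin",
            stacklevel=2,
        )
        k = 1
    edges = np.unique(np.quantile(scores, np.linspace(0, 1, k + 1)))
    if len(edges) < 3:
        groups = np.zeros(labels.size, dtype=int)
    else:
        # leftmost edge inclusive; interior edges close bins on the right
        groups = np.searchsorted(edges[1:-1], scores, side="left")
    bins = []
    frame = pd.DataFrame({"group": groups, "label": labels, "score": scores})
    for index, (_, grp) in enumerate(frame.groupby("group", sort=True), start=1):
        bins.append(
            CalibrationBin(
                index=index,
                n=int(len(grp)),
                mean_predicted=float(grp["score"].mean()),
                observed_fraction=float(grp["label"].mean()),
            )
        )
    return bins


def calibration_table(bins: list[CalibrationBin]) -> pd.DataFrame:
    """Bins as a DataFrame (columns: index, n, mean_predicted, observed_fraction)."""
    return pd.DataFrame(
        [
            {
                "index": b.index,
                "n": b.n,
                "mean_predicted": b.mean_predicted,
                "observed_fraction": b.observed_fraction,
            }
            for b in bins
        ]
    )
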