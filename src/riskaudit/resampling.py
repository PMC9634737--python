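"""Empirical (difference-method) bootstrap CIs and the CI-overlap rule.

The empirical bootstrap resamples records with replacement, forms the
differences ``d_b = theta*_b - theta_hat`` between each replicate statistic
and the point estimate, and subtracts difference percentiles from the point:
``CI = [theta_hat - q_{1-alpha/2}(d), theta_hat - q_{alpha/2}(d)]``.
Replicates on which the statistic is undefined (e.g. PPV with no flagged
records) are excluded from the percentiles and counted.  Bounds can fall
outside [0, 1] for extreme subgroups — that is a property of the method,
not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BootstrapSpec:
    """Bootstrap configuration: replicate count, CI level and seed."""

    b: int = 1000
    level: float = 0.95
    seed: int = 20220912

    def __post_init__(self):
        if self.b < 1:
            raise ValueError("bootstrap replicate count must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must lie in (0, 1)")


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    ci_low: float
    ci_high: float
    n_valid: int
    n_null: int

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.ci_low) or math.isnan(self.ci_high))


def _difference_ci(
    point: float, replicates: np.ndarray, b: int, level: float
) -> BootstrapCI:
    valid = replicates[~np.isnan(replicates)]
    n_valid = int(valid.size)
    n_null = int(b - n_valid)
    if n_valid == 0:
        return BootstrapCI(point, math.nan, math.nan, 0, n_null)
    alpha = 1 - level
    d = valid - point
    # inclusive empirical percentiles with linear interpolation
    q_low, q_high = np.percentile(d, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCI(point, float(point - q_high), float(point - q_low), n_valid, n_null)


def bootstrap_replicates(
    statistic: Callable[[pd.DataFrame], float],
    records: pd.DataFrame,
    spec: BootstrapSpec,
) -> np.ndarray:
    """Replicate values of ``statistic`` over B with-replacement resamples.

    NaN entries mark replicates on which the statistic was undefined.
    """
    if len(records) == 0:
        raise ValueError("records are empty")
    n = len(records)
    rng = np.random.default_rng(spec.seed)
    values = np.empty(spec.b)
    for i in range(spec.b):
        idx = rng.integers(0, n, size=n)
        values[i] = statistic(records.iloc[idx])
    return values


def empirical_bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float],
    records: pd.DataFrame,
    spec: BootstrapSpec,
) -> BootstrapCI:
    """Empirical bootstrap CI for an arbitrary record-level statistic.

    ``statistic`` maps a records DataFrame to a number, returning NaN where
    undefined.  It must be defined on the full input (otherwise no point
    estimate exists and a ``ValueError`` is raised).  Resampling is by
    record, with replacement, at the original size; identical seed, spec
    and data give a bit-identical interval.
    """
    if len(records) == 0:
        raise ValueError("records are empty")
    point = float(statistic(records))
    if math.isnan(point):
        raise ValueError("statistic is undefined on the full input; no CI possible")
    values = bootstrap_replicates(statistic, records, spec)
    return _difference_ci(point, values, spec.b, spec.level)


_CONFUSION_METRICS = ("sensitivity", "specificity", "ppv", "accuracy", "flag_rate")


def bootstrap_confusion_cis(
    labels,
    flags,
    spec: BootstrapSpec,
    metrics: Sequence[str] = _CONFUSION_METRICS,
) -> Mapping[str, BootstrapCI]:
    """Bootstrap CIs for confusion-matrix metrics, sharing one resample set.

    All requested metrics are evaluated on the same B resamples (as when a
    whole 2x2 table is recomputed per bootstrap sample), vectorized over
    replicates.  Metrics undefined on the full sample get a NaN point and
    an undefined CI rather than an error, since they are reported as rows
    of a larger table.
    """
    labels = np.asarray(labels, dtype=bool)
    flags = np.asarray(flags, dtype=bool)
    n = labels.size
    if n == 0:
        raise ValueError("records are empty")
    rng = np.random.default_rng(spec.seed)
    idx = rng.integers(0, n, size=(spec.b, n))
    lab = labels[idx]
    flg = flags[idx]
    tp = (lab & flg).sum(axis=1).astype(float)
    fp = (~lab & flg).sum(axis=1).astype(float)
    fn = (lab & ~flg).sum(axis=1).astype(float)
    tn = (~lab & ~flg).sum(axis=1).astype(float)

    def ratio(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
        return out

    full = {
        "sensitivity": (float((labels & flags).sum()), float(labels.sum())),
        "specificity": (float((~labels & ~flags).sum()), float((~labels).sum())),
        "ppv": (float((labels & flags).sum()), float(flags.sum())),
        "accuracy": (float((labels == flags).sum()), float(n)),
        "flag_rate": (float(flags.sum()), float(n)),
    }
    reps = {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "accuracy": ratio(tp + tn, tp + fp + fn + tn),
        "flag_rate": ratio(tp + fp, tp + fp + fn + tn),
    }
    out: dict[str, BootstrapCI] = {}
    for name in metrics:
        if name not in reps:
            raise ValueError(f"unknown confusion metric: {name!r}")
        num, den = full[name]
        if den == 0:
            out[name] = BootstrapCI(math.nan, math.nan, math.nan, 0, spec.b)
            continue
        out[name] = _difference_ci(num / den, reps[name], spec.b, spec.level)
    return out


def ci_disjoint(
    a: tuple[float, float], b: tuple[float, float]
) -> bool | None:
    """True iff two intervals do not overlap (touching endpoints overlap).

    Returns ``None`` (not assessable) when either interval is undefined.
    """
    a_low, a_high = a
    b_low, b_high = b
    if any(math.isnan(v) for v in (a_low, a_high, b_low, b_high)):
        return None
    return a_high < b_low or b_high < a_low
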