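"""Audit orchestration: overall and subgroup results, significance, reports.

``run_audit`` executes the full audit in order — per-subgroup counts and
prevalence with Clopper–Pearson intervals, overall confusion metrics with
empirical-bootstrap intervals, overall O/E with its delta-method interval
and binned calibration, then the same per subgroup — and applies the
CI-overlap significance rule and the small-sample ("inconclusive") rule.

Significance is a screening heuristic: a subgroup is flagged only when its
interval and the overall interval are both defined and disjoint.  Direction
follows the reporting convention of the audit tables: prevalence differences
are surfaced in both directions, performance only when lower, O/E only when
higher.  A metric whose defining denominator is below ``min_informative_n``
is additionally marked inconclusive (reported, never suppressed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from riskaudit._format import fmt_ci, fmt_fraction, fmt_oe
from riskaudit.calibration import CalibrationBin, OEResult, calibration_curve, oe_ratio
from riskaudit.cohort import AXES, AuditCohort, SubgroupDef, enumerate_subgroups
from riskaudit.metrics import MetricEstimate, confusion_from_flags, metric_from_counts, auroc, prevalence_cp_ci
from riskaudit.resampling import BootstrapSpec, bootstrap_confusion_cis, ci_disjoint

PERFORMANCE_METRICS = ("sensitivity", "specificity", "ppv", "accuracy", "flag_rate")
FLAG_NAMES = (
    "higher_prevalence",
    "lower_prevalence",
    "lower_sensitivity",
    "lower_specificity",
    "lower_ppv",
    "higher_oe",
)


@dataclass(frozen=True)
class AuditConfig:
    """Tunable audit parameters.

    ``threshold`` converts scores to flags (score >= threshold).
    ``min_informative_n`` is the smallest metric denominator treated as
    conclusive evidence (default 10).
    """

    threshold: float
    level: float = 0.95
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    calibration_bins: int = 5
    min_informative_n: int = 10
    axes: tuple[str, ...] = AXES
    include_unknown: bool = False

    def __post_init__(self):
        if self.min_informative_n < 1:
            raise ValueError("min_informative_n must be >= 1")


@dataclass
class SubgroupResult:
    """Audit results for one subgroup (or the overall cohort)."""

    name: str
    axis: str
    conditions: tuple[tuple[str, str], ...]
    n: int
    prevalence: MetricEstimate
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    accuracy: MetricEstimate
    flag_rate: MetricEstimate
    auroc: MetricEstimate
    oe: OEResult
    calibration: list[CalibrationBin]
    bootstrap_null_counts: dict[str, int] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)
    inconclusive: dict[str, bool] = field(default_factory=dict)

    @property
    def any_flag(self) -> bool:
        return any(self.flags.get(name, False) for name in FLAG_NAMES)


@dataclass
class AuditReport:
    setting_name: str
    model_id: str | None
    threshold: float
    level: float
    attrition: dict[str, int]
    overall: SubgroupResult
    subgroups: list[SubgroupResult]
    min_informative_n: int


def _subgroup_seed(base_seed: int, index: int) -> int:
    # deterministic per-subgroup stream, independent of subgroup sizes
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0])


def _compute_result(
    name: str,
    axis: str,
    conditions: tuple[tuple[str, str], ...],
    records: pd.DataFrame,
    config: AuditConfig,
    seed: int,
) -> SubgroupResult:
    labels = records["label"].to_numpy(dtype=int)
    flags = records["flag"].to_numpy(dtype=bool)
    scores = records["score"].to_numpy(dtype=float)
    counts = confusion_from_flags(labels, flags)

    spec = BootstrapSpec(b=config.bootstrap.b, level=config.level, seed=seed)
    boot = bootstrap_confusion_cis(labels, flags, spec, metrics=PERFORMANCE_METRICS)

    estimates = {}
    null_counts = {}
    for metric in PERFORMANCE_METRICS:
        est = metric_from_counts(metric, counts)
        ci = boot[metric]
        if est.defined and ci.defined:
            est = est.with_ci(ci.ci_low, ci.ci_high, "empirical_bootstrap")
        estimates[metric] = est
        null_counts[metric] = ci.n_null

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny subgroups collapse to one bin
        bins = calibration_curve(labels, scores, k=config.calibration_bins)

    return SubgroupResult(
        name=name,
        axis=axis,
        conditions=conditions,
        n=len(records),
        prevalence=prevalence_cp_ci(counts.positives, counts.n, level=config.level),
        sensitivity=estimates["sensitivity"],
        specificity=estimates["specificity"],
        ppv=estimates["ppv"],
        accuracy=estimates["accuracy"],
        flag_rate=estimates["flag_rate"],
        auroc=auroc(scores, labels),
        oe=oe_ratio(labels, scores, level=config.level),
        calibration=bins,
        bootstrap_null_counts=null_counts,
    )


def run_audit(cohort: AuditCohort, config: AuditConfig) -> AuditReport:
    """Run the full audit on a linked cohort; deterministic given the seed."""
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    records = cohort.records
    base_seed = config.bootstrap.seed

    overall = _compute_result(
        "Overall", "overall", (), records, config, _subgroup_seed(base_seed, 0)
    )
    defs = enumerate_subgroups(
        cohort, axes=config.axes, include_unknown=config.include_unknown
    )
    subgroups = []
    for i, sub_def in enumerate(defs, start=1):
        sub_records = records[sub_def.mask(records)]
        subgroups.append(
            _compute_result(
                sub_def.display_name,
                sub_def.axis,
                sub_def.conditions,
                sub_records,
                config,
                _subgroup_seed(base_seed, i),
            )
        )
    report = AuditReport(
        setting_name=cohort.setting_name,
        model_id=cohort.model_id,
        threshold=cohort.threshold,
        level=config.level,
        attrition=dict(cohort.attrition),
        overall=overall,
        subgroups=subgroups,
        min_informative_n=config.min_informative_n,
    )
    return flag_significance(report, config)


def _metric_ci(est: MetricEstimate) -> tuple[float, float]:
    return (est.ci_low, est.ci_high)


def flag_significance(report: AuditReport, config: AuditConfig) -> AuditReport:
    """Apply the CI-overlap rule and the small-sample rule to every subgroup."""
    overall = report.overall
    min_n = config.min_informative_n
    for sub in report.subgroups:
        flags = dict.fromkeys(FLAG_NAMES, False)

        prev_disjoint = ci_disjoint(_metric_ci(sub.prevalence), _metric_ci(overall.prevalence))
        if prev_disjoint:
            if sub.prevalence.value > overall.prevalence.value:
                flags["higher_prevalence"] = True
            elif sub.prevalence.value < overall.prevalence.value:
                flags["lower_prevalence"] = True

        for metric in ("sensitivity", "specificity", "ppv"):
            sub_est = getattr(sub, metric)
            over_est = getattr(overall, metric)
            disjoint = ci_disjoint(_metric_ci(sub_est), _metric_ci(over_est))
            if disjoint and sub_est.value < over_est.value:
                flags[f"lower_{metric}"] = True

        oe_disjoint = ci_disjoint(
            (sub.oe.ci_low, sub.oe.ci_high), (overall.oe.ci_low, overall.oe.ci_high)
        )
        if oe_disjoint and sub.oe.ratio > overall.oe.ratio:
            flags["higher_oe"] = True

        sub.flags = flags
        sub.inconclusive = {
            "prevalence": sub.n < min_n,
            "sensitivity": (sub.sensitivity.denominator or 0) < min_n,
            "specificity": (sub.specificity.denominator or 0) < min_n,
            "ppv": (sub.ppv.denominator or 0) < min_n,
            "oe": sub.n < min_n,
        }
    report.overall.flags = dict.fromkeys(FLAG_NAMES, False)
    report.overall.inconclusive = {
        "prevalence": overall.n < min_n,
        "sensitivity": (overall.sensitivity.denominator or 0) < min_n,
        "specificity": (overall.specificity.denominator or 0) < min_n,
        "ppv": (overall.ppv.denominator or 0) < min_n,
        "oe": overall.n < min_n,
    }
    return report


def _result_row(res: SubgroupResult) -> dict[str, str]:
    row = {"Group": res.name, "Sample Size": str(res.n)}
    for title, est in (
        ("Prevalence", res.prevalence),
        ("Sensitivity", res.sensitivity),
        ("Specificity", res.specificity),
        ("Positive Predictive Value", res.ppv),
    ):
        row[f"{title} (Fraction)"] = fmt_fraction(est.value, est.numerator, est.denominator)
        row[f"{title} [95% CI]"] = fmt_ci(est.ci_low, est.ci_high)
    row["O/E (Fraction)"] = fmt_oe(res.oe.ratio, res.oe.observed, res.oe.expected)
    row["O/E [95% CI]"] = fmt_ci(res.oe.ci_low, res.oe.ci_high, ndigits=1)
    row["Flags"] = ";".join(sorted(k for k, v in res.flags.items() if v))
    row["Inconclusive"] = ";".join(sorted(k for k, v in res.inconclusive.items() if v))
    return row


def significant_results_view(report: AuditReport) -> pd.DataFrame:
    """Overall row plus every subgroup carrying at least one flag.

    Mirrors the audit-table convention: prevalence differences in either
    direction, significantly *lower* performance, significantly *higher*
    O/E.  Inconclusive metrics are annotated, never suppressed.
    """
    rows = [_result_row(report.overall)]
    rows += [_result_row(sub) for sub in report.subgroups if sub.any_flag]
    return pd.DataFrame(rows)


def full_results_view(report: AuditReport) -> pd.DataFrame:
    """Formatted rows for the overall cohort and every subgroup."""
    rows = [_result_row(report.overall)]
    rows += [_result_row(sub) for sub in report.subgroups]
    return pd.DataFrame(rows)


def rebalance_cohort(cohort: AuditCohort, seed: int) -> AuditCohort:
    """Random oversampling of the minority label class to a 50/50 balance.

    Each minority record is duplicated ``floor(r)`` extra times plus a
    seeded random subset for the remainder, where ``r`` makes class counts
    equal.  With an integer ratio the duplication is exact, leaving
    sensitivity and specificity unchanged.
    """
    records = cohort.records
    labels = records["label"].to_numpy(dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present to rebalance")
    if n_pos == n_neg:
        return cohort.with_records(records.copy())
    minority = 1 if n_pos < n_neg else 0
    n_min, n_maj = min(n_pos, n_neg), max(n_pos, n_neg)
    extra = n_maj - n_min
    whole, rem = divmod(extra, n_min)
    minority_idx = records.index[labels == minority].to_numpy()
    dup_idx = np.repeat(minority_idx, whole)
    if rem:
        rng = np.random.default_rng(seed)
        dup_idx = np.concatenate(
            [dup_idx, np.sort(rng.choice(minority_idx, size=rem, replace=False))]
        )
    rebalanced = pd.concat([records, records.loc[dup_idx]], ignore_index=True)
    return cohort.with_records(rebalanced)


# --- serialization -------------------------------------------------------

def _estimate_to_dict(est: MetricEstimate) -> dict:
    return {
        "name": est.name,
        "value": est.value,
        "numerator": est.numerator,
        "denominator": est.denominator,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "ci_method": est.ci_method,
    }


def _estimate_from_dict(d: dict) -> MetricEstimate:
    return MetricEstimate(**d)


def _result_to_dict(res: SubgroupResult) -> dict:
    return {
        "name": res.name,
        "axis": res.axis,
        "conditions": [list(c) for c in res.conditions],
        "n": res.n,
        "estimates": {
            key: _estimate_to_dict(getattr(res, key))
            for key in ("prevalence", *PERFORMANCE_METRICS, "auroc")
        },
        "oe": {
            "observed": res.oe.observed,
            "expected": res.oe.expected,
            "n": res.oe.n,
            "ratio": res.oe.ratio,
            "ci_low": res.oe.ci_low,
            "ci_high": res.oe.ci_high,
            "level": res.oe.level,
        },
        "calibration": [
            {
                "index": b.index,
                "n": b.n,
                "mean_predicted": b.mean_predicted,
                "observed_fraction": b.observed_fraction,
            }
            for b in res.calibration
        ],
        "bootstrap_null_counts": res.bootstrap_null_counts,
        "flags": res.flags,
        "inconclusive": res.inconclusive,
    }


def _result_from_dict(d: dict) -> SubgroupResult:
    est = {key: _estimate_from_dict(val) for key, val in d["estimates"].items()}
    return SubgroupResult(
        name=d["name"],
        axis=d["axis"],
        conditions=tuple(tuple(c) for c in d["conditions"]),
        n=d["n"],
        prevalence=est["prevalence"],
        sensitivity=est["sensitivity"],
        specificity=est["specificity"],
        ppv=est["ppv"],
        accuracy=est["accuracy"],
        flag_rate=est["flag_rate"],
        auroc=est["auroc"],
        oe=OEResult(**d["oe"]),
        calibration=[CalibrationBin(**b) for b in d["calibration"]],
        bootstrap_null_counts=dict(d["bootstrap_null_counts"]),
        flags=dict(d["flags"]),
        inconclusive=dict(d["inconclusive"]),
    )


def report_to_json(report: AuditReport) -> str:
    payload = {
        "setting_name": report.setting_name,
        "model_id": report.model_id,
        "threshold": report.threshold,
        "level": report.level,
        "attrition": report.attrition,
        "min_informative_n": report.min_informative_n,
        "overall": _result_to_dict(report.overall),
        "subgroups": [_result_to_dict(s) for s in report.subgroups],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def report_from_json(text: str) -> AuditReport:
    d = json.loads(text, parse_constant=lambda s: float(s))
    return AuditReport(
        setting_name=d["setting_name"],
        model_id=d["model_id"],
        threshold=d["threshold"],
        level=d["level"],
        attrition={k: int(v) for k, v in d["attrition"].items()},
        overall=_result_from_dict(d["overall"]),
        subgroups=[_result_from_dict(s) for s in d["subgroups"]],
        min_informative_n=d["min_informative_n"],
    )


def _metrics_csv(report: AuditReport) -> str:
    rows = []
    for res in [report.overall, *report.subgroups]:
        for key in ("prevalence", *PERFORMANCE_METRICS, "auroc"):
            est: MetricEstimate = getattr(res, key)
            rows.append(
                {
                    "group": res.name,
                    "name": est.name,
                    "value": est.value,
                    "numerator": est.numerator,
                    "denominator": est.denominator,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "ci_method": est.ci_method,
                }
            )
        rows.append(
            {
                "group": res.name,
                "name": "oe_ratio",
                "value": res.oe.ratio,
                "numerator": res.oe.observed,
                "denominator": res.oe.expected,
                "ci_low": res.oe.ci_low,
                "ci_high": res.oe.ci_high,
                "ci_method": "delta_method",
            }
        )
    return pd.DataFrame(rows).to_csv(index=False)


def _calibration_csv(report: AuditReport) -> str:
    rows = []
    for res in [report.overall, *report.subgroups]:
        for b in res.calibration:
            rows.append(
                {
                    "group": res.name,
                    "index": b.index,
                    "n": b.n,
                    "mean_predicted": b.mean_predicted,
                    "observed_fraction": b.observed_fraction,
                }
            )
    return pd.DataFrame(rows).to_csv(index=False)


def _markdown(report: AuditReport) -> str:
    def table(df: pd.DataFrame) -> str:
        header = "| " + " | ".join(df.columns) + " |"
        sep = "| " + " | ".join("---" for _ in df.columns) + " |"
        body = ["| " + " | ".join(map(str, row)) + " |" for row in df.to_numpy()]
        return "\n".join([header, sep, *body])

    title = report.setting_name or "Audit report"
    lines = [
        f"# {title}",
        "",
        f"Model: {report.model_id}; threshold: {report.threshold}; "
        f"CI level: {report.level}",
        "",
        "## Attrition",
        "",
        *[f"- {k}: {v}" for k, v in report.attrition.items()],
        "",
        "## Significant results",
        "",
        table(significant_results_view(report)),
        "",
        "## All subgroups",
        "",
        table(full_results_view(report)),
        "",
    ]
    return "\n".join(lines)


def render_report(
    report: AuditReport,
    format: str = "markdown",
    out_dir=None,
) -> dict[str, str]:
    """Serialize the report; returns ``{filename: content}`` and optionally writes.

    Formats: ``markdown`` (report.md), ``csv`` (metrics.csv, subgroups.csv,
    calibration_bins.csv), ``json`` (report.json, lossless round-trip).
    """
    if format == "markdown":
        files = {"report.md": _markdown(report)}
    elif format == "csv":
        files = {
            "metrics.csv": _metrics_csv(report),
            "subgroups.csv": significant_results_view(report).to_csv(index=False),
            "calibration_bins.csv": _calibration_csv(report),
        }
    elif format == "json":
        files = {"report.json": report_to_json(report)}
    else:
        raise ValueError(f"unknown report format: {format!r}")
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, content in files.items():
            (out / name).write_text(content)
    return files
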