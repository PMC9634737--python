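"""Synthetic cohorts with known ground truth for end-to-end testing.

Two generators:

* :func:`generate_cohort` draws a full three-table cohort (labels,
  predictions, demographics) from a configurable demographic mixture with
  per-subgroup label prevalence and a controllable O/E miscalibration
  target, so that parameter recovery (does the audit detect a stratum
  generated at O/E = 3?) can be tested without any clinical data.
* :func:`fixture_from_counts` reconstructs a linked cohort exactly matching
  a printed 2x2 table and expected-event total, for worked examples.

Both are fully reproducible from their seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from riskaudit.cohort import AuditCohort, age_and_bin

#: Default marginal demographic mixture.  Roughly emulates the adult patient
#: mix of a large US academic health system; Unknown levels are omitted by
#: default so every generated record contributes to subgroup axes.
DEFAULT_SEX_MIX: Mapping[str, float] = {"Female": 0.52, "Male": 0.48}
DEFAULT_ETHNICITY_RACE_MIX: Mapping[tuple[str, str], float] = {
    ("Not Hispanic or Latino", "White"): 0.44,
    ("Not Hispanic or Latino", "Asian"): 0.17,
    ("Not Hispanic or Latino", "Black or African American"): 0.05,
    ("Not Hispanic or Latino", "Other"): 0.09,
    ("Not Hispanic or Latino", "Native Hawaiian or Other Pacific Islander"): 0.02,
    ("Not Hispanic or Latino", "American Indian or Alaska Native"): 0.01,
    ("Hispanic or Latino", "Other"): 0.13,
    ("Hispanic or Latino", "White"): 0.09,
}
#: Decade lower bounds and weights for age at assessment.
DEFAULT_AGE_DECADE_MIX: Mapping[int, float] = {
    20: 0.08,
    30: 0.12,
    40: 0.13,
    50: 0.17,
    60: 0.20,
    70: 0.16,
    80: 0.10,
    90: 0.04,
}

REFERENCE_DATE = dt.date(2022, 3, 1)


@dataclass(frozen=True)
class CohortSimConfig:
    """Study conditions for a simulated audit cohort.

    Defaults mirror a primary-care-style validation: n = 338 records with a
    20% positive-label prevalence.  Class-conditional scores are Beta
    distributed with realistic overlap (AUROC around 0.8–0.85), then
    rescaled multiplicatively so the expected O/E matches ``oe_target``
    (subgroup overrides supported), clipping at 1 with infeasibility
    detected rather than silently truncated.

    Override keys are tuples of ``(attribute, value)`` pairs, e.g.
    ``((("ethnicity", "Hispanic or Latino"), ("race", "Other")),)``.
    """

    n: int = 338
    base_prevalence: float = 0.2
    subgroup_prevalence_overrides: Mapping[tuple, float] = field(default_factory=dict)
    beta_pos: tuple[float, float] = (3.0, 3.0)
    beta_neg: tuple[float, float] = (1.5, 4.0)
    oe_target: float = 1.0
    subgroup_oe_overrides: Mapping[tuple, float] = field(default_factory=dict)
    sex_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_MIX))
    ethnicity_race_mix: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ETHNICITY_RACE_MIX)
    )
    age_decade_mix: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_DECADE_MIX)
    )
    model_id: str = "synthetic-model"
    horizon_years: float = 1.0
    seed: int = 20220912

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 < self.base_prevalence < 1:
            raise ValueError("base_prevalence must lie in (0, 1)")
        for p in self.subgroup_prevalence_overrides.values():
            if not 0 < p < 1:
                raise ValueError("subgroup prevalences must lie in (0, 1)")
        if self.oe_target <= 0:
            raise ValueError("oe_target must be positive")
        for name, mix in (
            ("sex_mix", self.sex_mix),
            ("ethnicity_race_mix", self.ethnicity_race_mix),
            ("age_decade_mix", self.age_decade_mix),
        ):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")


@dataclass
class SimulatedTables:
    """The three input tables plus the realized ground truth."""

    labels: pd.DataFrame
    predictions: pd.DataFrame
    demographics: pd.DataFrame
    truth: dict


class InfeasibleOETargetError(ValueError):
    """The requested O/E target cannot be met after clipping scores at 1."""


def _sample_categorical(rng, items: Sequence, probs: Sequence[float], size: int):
    idx = rng.choice(len(items), size=size, p=np.asarray(probs, dtype=float))
    return [items[i] for i in idx]


def _conditions_mask(frame: pd.DataFrame, conditions: tuple) -> np.ndarray:
    mask = np.ones(len(frame), dtype=bool)
    for attr, value in conditions:
        mask &= (frame[attr] == value).to_numpy()
    return mask


def generate_cohort(config: CohortSimConfig) -> SimulatedTables:
    """Draw labels, predictions and demographics with known parameters.

    Per record: demographics from the mixture, label ~ Bernoulli(subgroup
    prevalence), score from the class-conditional Beta, then a
    multiplicative rescale per O/E stratum so that the stratum's score sum
    equals its observed events divided by the stratum's O/E target.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    sexes = _sample_categorical(
        rng, list(config.sex_mix), list(config.sex_mix.values()), n
    )
    eth_race = _sample_categorical(
        rng, list(config.ethnicity_race_mix), list(config.ethnicity_race_mix.values()), n
    )
    decades = _sample_categorical(
        rng, list(config.age_decade_mix), list(config.age_decade_mix.values()), n
    )
    ages = np.array([d + int(rng.integers(1, 11)) for d in decades])

    frame = pd.DataFrame(
        {
            "patient_id": [f"pt-{i:06d}" for i in range(n)],
            "sex": sexes,
            "ethnicity": [er[0] for er in eth_race],
            "race": [er[1] for er in eth_race],
            "age_years": ages,
        }
    )

    prevalence = np.full(n, config.base_prevalence)
    for conditions, p in config.subgroup_prevalence_overrides.items():
        prevalence[_conditions_mask(frame, conditions)] = p
    labels = (rng.random(n) < prevalence).astype(int)

    a1, b1 = config.beta_pos
    a0, b0 = config.beta_neg
    scores = np.where(labels == 1, rng.beta(a1, b1, size=n), rng.beta(a0, b0, size=n))

    # assign each record to exactly one O/E stratum (first matching override)
    stratum = np.full(n, -1, dtype=int)
    targets = []
    for s_idx, (conditions, oe) in enumerate(config.subgroup_oe_overrides.items()):
        mask = _conditions_mask(frame, conditions) & (stratum == -1)
        stratum[mask] = s_idx
        targets.append((conditions, oe, s_idx))
    truth_strata = {}
    for conditions, oe, s_idx in [*targets, (None, config.oe_target, -1)]:
        mask = stratum == s_idx
        if not mask.any():
            continue
        observed = labels[mask].sum()
        raw_sum = scores[mask].sum()
        target_e = observed / oe
        scale = 0.0 if raw_sum == 0 else target_e / raw_sum
        rescaled = np.clip(scores[mask] * scale, 0.0, 1.0)
        achieved = rescaled.sum()
        name = "base" if conditions is None else ", ".join(f"{a}={v}" for a, v in conditions)
        if target_e > 0 and abs(achieved - target_e) / target_e > 0.02:
            raise InfeasibleOETargetError(
                f"O/E target {oe} infeasible for stratum {name}: "
                f"needed E={target_e:.2f}, achievable E={achieved:.2f} after clipping"
            )
        scores[mask] = rescaled
        truth_strata[name] = {
            "oe_target": oe,
            "n": int(mask.sum()),
            "observed": int(observed),
            "expected": float(achieved),
        }

    response_date = REFERENCE_DATE
    dobs = [
        dt.date(response_date.year - int(age), 1, 1)
        + dt.timedelta(days=int(rng.integers(0, 59)))
        for age in ages
    ]  # dob on/before the reference month/day, so completed age == drawn age

    labels_table = pd.DataFrame(
        {
            "clinician_id": [f"clin-{i % 20:03d}" for i in range(n)],
            "patient_id": frame["patient_id"],
            "response_date": [response_date.isoformat()] * n,
            "answer": np.where(labels == 1, "No", "Yes"),
        }
    )
    predictions_table = pd.DataFrame(
        {
            "patient_id": frame["patient_id"],
            "model_id": config.model_id,
            "score_date": [(response_date - dt.timedelta(days=1)).isoformat()] * n,
            "score": scores,
        }
    )
    demographics_table = pd.DataFrame(
        {
            "patient_id": frame["patient_id"],
            "sex": frame["sex"],
            "date_of_birth": [d.isoformat() for d in dobs],
            "ethnicity": frame["ethnicity"],
            "race": frame["race"],
        }
    )
    truth = {
        "config": {
            "n": n,
            "base_prevalence": config.base_prevalence,
            "oe_target": config.oe_target,
            "seed": config.seed,
        },
        "labels": labels.tolist(),
        "strata": truth_strata,
        "overall": {
            "observed": int(labels.sum()),
            "expected": float(scores.sum()),
        },
    }
    return SimulatedTables(
        labels=labels_table,
        predictions=predictions_table,
        demographics=demographics_table,
        truth=truth,
    )


def fixture_from_counts(
    tp: int,
    fp: int,
    fn: int,
    tn: int,
    e_target: float,
    threshold: float,
    *,
    model_id: str = "fixture",
    setting_name: str = "",
    sex: str = "Female",
    ethnicity: str = "Not Hispanic or Latino",
    race: str = "White",
    age_years: int = 65,
) -> AuditCohort:
    """A linked cohort reproducing a printed 2x2 table and expected events.

    Emits exactly ``tp + fp + fn + tn`` records whose flags and labels
    match the counts; flagged records score at or above the threshold,
    unflagged strictly below, and all scores sum to ``e_target``.  All
    records share one demographic profile (the fixture exercises overall
    metrics, not subgroup structure).
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if e_target < 0:
        raise ValueError("e_target must be non-negative")
    flagged = tp + fp
    unflagged = fn + tn
    n = flagged + unflagged
    if n == 0:
        raise ValueError("at least one record is required")

    if flagged == 0:
        s_flagged = 0.0
        s_unflagged = e_target / unflagged if unflagged else 0.0
        if s_unflagged >= threshold:
            raise InfeasibleOETargetError(
                f"expected events {e_target} unreachable with no flagged records "
                f"below threshold {threshold}"
            )
    elif unflagged == 0:
        s_unflagged = 0.0
        s_flagged = e_target / flagged
        if not threshold <= s_flagged <= 1:
            raise InfeasibleOETargetError(
                f"expected events {e_target} unreachable with {flagged} flagged "
                f"records at threshold {threshold}"
            )
    else:
        s_unflagged = (e_target - flagged * threshold) / unflagged
        if s_unflagged < 0:
            s_unflagged = 0.0
            s_flagged = e_target / flagged
        elif s_unflagged >= threshold:
            s_unflagged = threshold * (1 - 1e-9)
            s_flagged = (e_target - unflagged * s_unflagged) / flagged
        else:
            s_flagged = threshold
        if not threshold <= s_flagged <= 1:
            raise InfeasibleOETargetError(
                f"expected events {e_target} inconsistent with {flagged} flagged / "
                f"{unflagged} unflagged records at threshold {threshold}"
            )

    rows = []
    label_date = REFERENCE_DATE
    dob = dt.date(label_date.year - age_years, 1, 1)
    _, age_bin = age_and_bin(dob, label_date)
    blocks = (
        (tp, 1, 1, s_flagged),
        (fp, 0, 1, s_flagged),
        (fn, 1, 0, s_unflagged),
        (tn, 0, 0, s_unflagged),
    )
    i = 0
    for count, label, flag, score in blocks:
        for _ in range(count):
            rows.append(
                {
                    "patient_id": f"fx-{i:06d}",
                    "label_date": label_date,
                    "label": label,
                    "score": score,
                    "flag": flag,
                    "sex": sex,
                    "ethnicity": ethnicity,
                    "race": race,
                    "age_years": age_years,
                    "age_bin": age_bin,
                }
            )
            i += 1
    records = pd.DataFrame(rows)
    return AuditCohort(
        records=records,
        model_id=model_id,
        threshold=threshold,
        setting_name=setting_name,
        attrition={"labels_in": n, "no_prediction": 0, "no_demographics": 0, "final": n},
    )
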