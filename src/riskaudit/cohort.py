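"""Cohort assembly: parse label/prediction/demographic tables and link them.

The audit cohort is built from three flat tables:

* clinician surprise-question answers (``clinician_id, patient_id,
  response_date, answer``) — an answer of "No" ("would *not* be surprised if
  the patient passed away within the horizon") is the positive label;
* model prediction records (``patient_id, model_id, score_date, score``);
* patient demographics (``patient_id, sex, date_of_birth, ethnicity, race``)
  with sex/ethnicity/race drawn from fixed OMB-style vocabularies.

The unit of analysis is the label record, not the patient: repeat
hospitalizations yield repeat records and all are kept.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SEX_LEVELS = ("Female", "Male", "Unknown")
ETHNICITY_LEVELS = ("Hispanic or Latino", "Not Hispanic or Latino", "Unknown")
RACE_LEVELS = (
    "White",
    "Black or African American",
    "Asian",
    "Native Hawaiian or Other Pacific Islander",
    "American Indian or Alaska Native",
    "Other",
    "Unknown",
)

#: Default mapping from normalized (lower-cased, stripped) answer text to the
#: binary label.  "No" means the clinician would NOT be surprised by death
#: within the horizon, i.e. the positive label.
DEFAULT_ANSWER_MAP: Mapping[str, int] = {"no": 1, "yes": 0}

LABEL_COLUMNS = ("clinician_id", "patient_id", "response_date", "answer")
PREDICTION_COLUMNS = ("patient_id", "model_id", "score_date", "score")
DEMOGRAPHIC_COLUMNS = ("patient_id", "sex", "date_of_birth", "ethnicity", "race")

AXES = ("sex", "age", "ethnicity_race", "ethnicity_race_sex")

_AXIS_ATTRS = {
    "sex": ("sex",),
    "age": ("age_bin",),
    "ethnicity_race": ("ethnicity", "race"),
    "ethnicity_race_sex": ("ethnicity", "race", "sex"),
}

_ATTR_TITLES = {"sex": "Sex", "age_bin": "Age", "ethnicity": "Ethnicity", "race": "Race"}


class InputSchemaError(ValueError):
    """An input table is missing a required column or violates its schema."""


class DuplicateDemographicsError(InputSchemaError):
    """More than one demographics row exists for the same patient."""

    def __init__(self, patient_ids: Sequence[str]):
        self.patient_ids = list(patient_ids)
        super().__init__(
            "duplicate demographics rows for patient ids: "
            + ", ".join(map(str, self.patient_ids))
        )


def _require_columns(table: pd.DataFrame, required: Iterable[str], name: str) -> None:
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise InputSchemaError(
            f"{name} table is missing required column(s): {', '.join(missing)}"
        )


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return pd.Timestamp(value).date()


@dataclass(frozen=True)
class SubgroupDef:
    """A named conjunction of demographic attribute values.

    ``axis`` is one of ``sex``, ``age``, ``ethnicity_race``,
    ``ethnicity_race_sex``; ``conditions`` is a tuple of
    ``(attribute, value)`` pairs combined with logical AND.
    """

    axis: str
    conditions: tuple[tuple[str, str], ...]

    @property
    def display_name(self) -> str:
        return ", ".join(
            f"{_ATTR_TITLES[attr]}: {value}" for attr, value in self.conditions
        )

    def mask(self, records: pd.DataFrame) -> pd.Series:
        m = pd.Series(True, index=records.index)
        for attr, value in self.conditions:
            m &= records[attr] == value
        return m


@dataclass
class AuditCohort:
    """Linked audit records plus linkage attrition accounting.

    ``records`` has one row per clinician label that linked successfully;
    columns: ``patient_id, label_date, label, score, flag, sex, ethnicity,
    race, age_years, age_bin``.
    """

    records: pd.DataFrame
    model_id: str | None = None
    threshold: float = 0.5
    setting_name: str = ""
    attrition: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.records)

    def with_records(self, records: pd.DataFrame) -> "AuditCohort":
        return AuditCohort(
            records=records.reset_index(drop=True),
            model_id=self.model_id,
            threshold=self.threshold,
            setting_name=self.setting_name,
            attrition=dict(self.attrition),
        )


def parse_surprise_answers(
    raw_table: pd.DataFrame,
    answer_map: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert raw surprise-question answers into binary labels.

    Answers are matched case-insensitively (leading/trailing whitespace
    stripped) against ``answer_map`` (default: "no" -> 1, "yes" -> 0).  Rows
    whose answer is not in the map — e.g. "Maybe", "TRANSFERRED", "Y/N",
    "DECEASED" — are rejected with the literal offending text recorded.

    Returns ``(valid, rejected)``; ``valid`` has columns ``patient_id,
    label_date, label``, ``rejected`` the original columns plus ``reason``.
    """
    _require_columns(raw_table, LABEL_COLUMNS, "labels")
    answer_map = DEFAULT_ANSWER_MAP if answer_map is None else answer_map
    norm_map = {str(k).strip().lower(): int(v) for k, v in answer_map.items()}

    answers = raw_table["answer"].astype(str).str.strip().str.lower()
    ok = answers.isin(norm_map)

    valid = pd.DataFrame(
        {
            "patient_id": raw_table.loc[ok, "patient_id"].to_numpy(),
            "label_date": [
                _as_date(v) for v in raw_table.loc[ok, "response_date"]
            ],
            "label": answers[ok].map(norm_map).astype(int).to_numpy(),
        }
    )
    rejected = raw_table.loc[~ok].copy()
    rejected["reason"] = [
        f"answer not in schema: {text!r}" for text in rejected["answer"].astype(str)
    ]
    return valid.reset_index(drop=True), rejected.reset_index(drop=True)


def age_and_bin(date_of_birth: dt.date, reference_date: dt.date) -> tuple[int, str]:
    """Completed-years age at ``reference_date`` and its decade bin.

    Age is computed by calendar (month/day) comparison, not day-count
    division.  Bins are half-open below and closed above — ``(a, a+10]``
    — so age 80 falls in ``(70, 80]``.
    """
    dob = _as_date(date_of_birth)
    ref = _as_date(reference_date)
    if ref < dob:
        raise ValueError(
            f"reference date {ref.isoformat()} precedes date of birth {dob.isoformat()}"
        )
    age = ref.year - dob.year - ((ref.month, ref.day) < (dob.month, dob.day))
    lower = ((age - 1) // 10) * 10  # a < age <= a + 10
    return age, f"({lower}, {lower + 10}]"


def _validate_categories(demographics: pd.DataFrame) -> pd.DataFrame:
    demo = demographics.copy()
    for col, levels in (
        ("sex", SEX_LEVELS),
        ("ethnicity", ETHNICITY_LEVELS),
        ("race", RACE_LEVELS),
    ):
        demo[col] = demo[col].fillna("Unknown").replace("", "Unknown")
        bad = sorted(set(demo[col]) - set(levels))
        if bad:
            raise InputSchemaError(
                f"unrecognized {col} value(s): {bad}; expected one of {levels}"
            )
    return demo


def link_records(
    labels: pd.DataFrame,
    predictions: pd.DataFrame,
    demographics: pd.DataFrame,
    *,
    threshold: float,
    model_id: str | None = None,
    policy: str = "most_recent_on_or_before",
    setting_name: str = "",
) -> AuditCohort:
    """Link binary labels with a model prediction and demographics.

    ``labels`` must be the validated output of :func:`parse_surprise_answers`
    (columns ``patient_id, label_date, label``).  Prediction selection
    ``policy``:

    * ``"most_recent_on_or_before"`` — the most recent score dated on or
      before the label date;
    * ``"snapshot"`` — the single fixed-date score per patient (an error if a
      patient has several).

    Labels lacking an eligible prediction or a demographics row are dropped
    and counted in ``attrition``; no record is ever fabricated.
    """
    _require_columns(labels, ("patient_id", "label_date", "label"), "labels")
    _require_columns(predictions, PREDICTION_COLUMNS, "predictions")
    _require_columns(demographics, DEMOGRAPHIC_COLUMNS, "demographics")
    if policy not in ("most_recent_on_or_before", "snapshot"):
        raise ValueError(f"unknown linkage policy: {policy!r}")

    preds = predictions
    if model_id is not None:
        preds = preds[preds["model_id"] == model_id]
    preds = preds.copy()
    preds["score_date"] = [_as_date(v) for v in preds["score_date"]]
    if ((preds["score"] < 0) | (preds["score"] > 1)).any():
        raise InputSchemaError("prediction scores must lie in [0, 1]")

    demo = _validate_categories(demographics)
    dup = demo["patient_id"][demo["patient_id"].duplicated()]
    if len(dup):
        raise DuplicateDemographicsError(sorted(set(dup)))
    demo = demo.set_index("patient_id")

    if policy == "snapshot":
        multi = preds["patient_id"][preds["patient_id"].duplicated()]
        if len(multi):
            raise InputSchemaError(
                "snapshot policy requires a single prediction per patient; "
                f"duplicated patient ids: {sorted(set(multi))}"
            )
    by_patient = {pid: grp for pid, grp in preds.groupby("patient_id", sort=False)}

    rows = []
    no_prediction = 0
    no_demographics = 0
    for label_row in labels.itertuples(index=False):
        pid = label_row.patient_id
        label_date = _as_date(label_row.label_date)
        grp = by_patient.get(pid)
        if grp is None:
            no_prediction += 1
            continue
        if policy == "most_recent_on_or_before":
            eligible = grp[grp["score_date"] <= label_date]
            if eligible.empty:
                no_prediction += 1
                continue
            chosen = eligible.loc[eligible["score_date"].idxmax()]
        else:  # snapshot
            chosen = grp.iloc[0]
        if pid not in demo.index:
            no_demographics += 1
            continue
        d = demo.loc[pid]
        age, age_bin = age_and_bin(d["date_of_birth"], label_date)
        score = float(chosen["score"])
        rows.append(
            {
                "patient_id": pid,
                "label_date": label_date,
                "label": int(label_row.label),
                "score": score,
                "flag": int(score >= threshold),
                "sex": d["sex"],
                "ethnicity": d["ethnicity"],
                "race": d["race"],
                "age_years": age,
                "age_bin": age_bin,
            }
        )

    records = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "label_date",
            "label",
            "score",
            "flag",
            "sex",
            "ethnicity",
            "race",
            "age_years",
            "age_bin",
        ],
    )
    attrition = {
        "labels_in": len(labels),
        "no_prediction": no_prediction,
        "no_demographics": no_demographics,
        "final": len(records),
    }
    return AuditCohort(
        records=records,
        model_id=model_id,
        threshold=threshold,
        setting_name=setting_name,
        attrition=attrition,
    )


def _age_sort_key(value: str) -> tuple:
    # "(70, 80]" -> 70; keeps decade bins in numeric order
    return (int(value.split(",")[0][1:]),)


def enumerate_subgroups(
    cohort: AuditCohort,
    axes: Sequence[str] = AXES,
    include_unknown: bool = False,
) -> list[SubgroupDef]:
    """All observed demographic subgroups, per axis.

    Only combinations actually present in the cohort are returned ("observed
    permutations").  By default, subgroups involving an ``Unknown`` level are
    omitted; pass ``include_unknown=True`` to keep them.  Ordering is
    deterministic: axis order as given, then value order within the axis
    (numeric for age bins, lexicographic otherwise).
    """
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    records = cohort.records
    out: list[SubgroupDef] = []
    for axis in axes:
        if axis not in _AXIS_ATTRS:
            raise ValueError(f"unknown subgroup axis: {axis!r}")
        attrs = _AXIS_ATTRS[axis]
        observed = {
            tuple(combo) for combo in records[list(attrs)].drop_duplicates().to_numpy()
        }
        if not include_unknown:
            observed = {c for c in observed if "Unknown" not in c}
        key = (
            (lambda combo: _age_sort_key(combo[0]))
            if axis == "age"
            else (lambda combo: combo)
        )
        for combo in sorted(observed, key=key):
            out.append(
                SubgroupDef(axis=axis, conditions=tuple(zip(attrs, combo)))
            )
    return out
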