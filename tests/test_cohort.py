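"""Cohort assembly: answer parsing, linkage, age binning, subgroup enumeration."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskaudit import AuditCohort, age_and_bin, enumerate_subgroups, link_records, parse_surprise_answers
from riskaudit.cohort import DuplicateDemographicsError, InputSchemaError
from conftest import make_records


def label_table(answers, patient_ids=None, date="2022-03-01"):
    n = len(answers)
    return pd.DataFrame(
        {
            "clinician_id": ["c1"] * n,
            "patient_id": patient_ids or [f"p{i}" for i in range(n)],
            "response_date": [date] * n,
            "answer": answers,
        }
    )


class TestParseSurpriseAnswers:
    def test_yes_no_mapped_others_rejected_verbatim(self):
        valid, rejected = parse_surprise_answers(
            label_table(["No", "Yes", "Maybe", "TRANSFERRED"])
        )
        assert list(valid["label"]) == [1, 0]
        assert len(rejected) == 2
        assert "'Maybe'" in rejected["reason"].iloc[0]
        assert "'TRANSFERRED'" in rejected["reason"].iloc[1]

    def test_case_and_whitespace_insensitive(self):
        valid, rejected = parse_surprise_answers(label_table([" NO ", "yes", "nO"]))
        assert list(valid["label"]) == [1, 0, 1]
        assert rejected.empty

    def test_empty_table(self):
        valid, rejected = parse_surprise_answers(label_table([]))
        assert len(valid) == 0 and len(rejected) == 0

    def test_344_rows_with_6_invalid_leaves_338(self):
        # mirrors a primary-care style harvest: 6 off-schema answers dropped
        answers = ["No"] * 68 + ["Yes"] * 270 + ["Y/N"] * 4 + ["DECEASED"] * 2
        valid, rejected = parse_surprise_answers(label_table(answers))
        assert len(valid) == 338
        assert len(rejected) == 6
        assert valid["label"].sum() == 68

    def test_missing_column_error_names_column(self):
        with pytest.raises(InputSchemaError, match="answer"):
            parse_surprise_answers(
                pd.DataFrame({"clinician_id": [], "patient_id": [], "response_date": []})
            )

    @given(
        n_no=st.integers(0, 30),
        n_yes=st.integers(0, 30),
        n_bad=st.integers(0, 30),
    )
    @settings(max_examples=25, deadline=None)
    def test_partition_conservation(self, n_no, n_yes, n_bad):
        answers = ["No"] * n_no + ["Yes"] * n_yes + ["??"] * n_bad
        valid, rejected = parse_surprise_answers(label_table(answers))
        assert len(valid) + len(rejected) == len(answers)
        assert len(valid) == n_no + n_yes


def demo_row(pid, sex="Female", dob="1950-06-15", ethnicity="Not Hispanic or Latino", race="White"):
    return {
        "patient_id": pid,
        "sex": sex,
        "date_of_birth": dob,
        "ethnicity": ethnicity,
        "race": race,
    }


def pred_row(pid, score, date="2022-02-28", model_id="m"):
    return {"patient_id": pid, "model_id": model_id, "score_date": date, "score": score}


class TestLinkRecords:
    def test_attrition_accounting_202_labels_to_150(self):
        # 202 validated labels; 40 lack predictions, 12 lack demographics
        labels = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(202)],
                "label_date": [dt.date(2022, 3, 1)] * 202,
                "label": [i % 2 for i in range(202)],
            }
        )
        preds = pd.DataFrame([pred_row(f"p{i}", 0.4) for i in range(162)])
        demos = pd.DataFrame(
            [demo_row(f"p{i}") for i in range(150)] + [demo_row(f"p{i}") for i in range(162, 202)]
        )
        cohort = link_records(labels, preds, demos, threshold=0.45)
        assert cohort.n == 150
        assert cohort.attrition["no_prediction"] == 40
        assert cohort.attrition["no_demographics"] == 12
        # conservation: final + attrition = labels in
        assert (
            cohort.attrition["final"]
            + cohort.attrition["no_prediction"]
            + cohort.attrition["no_demographics"]
            == cohort.attrition["labels_in"]
        )

    def test_label_before_every_prediction_excluded(self):
        labels = pd.DataFrame(
            {"patient_id": ["p0"], "label_date": [dt.date(2022, 1, 1)], "label": [1]}
        )
        preds = pd.DataFrame([pred_row("p0", 0.9, date="2022-02-01")])
        demos = pd.DataFrame([demo_row("p0")])
        cohort = link_records(labels, preds, demos, threshold=0.5)
        assert cohort.n == 0
        assert cohort.attrition["no_prediction"] == 1

    def test_most_recent_on_or_before_selects_day1_score(self):
        labels = pd.DataFrame(
            {"patient_id": ["p0"], "label_date": [dt.date(2022, 3, 4)], "label": [1]}
        )
        preds = pd.DataFrame(
            [pred_row("p0", 0.10, date="2022-03-01"), pred_row("p0", 0.90, date="2022-03-05")]
        )
        demos = pd.DataFrame([demo_row("p0")])
        cohort = link_records(labels, preds, demos, threshold=0.5)
        assert cohort.records["score"].iloc[0] == 0.10

    def test_snapshot_policy_rejects_multiple_predictions(self):
        labels = pd.DataFrame(
            {"patient_id": ["p0"], "label_date": [dt.date(2022, 3, 4)], "label": [1]}
        )
        preds = pd.DataFrame([pred_row("p0", 0.1), pred_row("p0", 0.2)])
        demos = pd.DataFrame([demo_row("p0")])
        with pytest.raises(InputSchemaError, match="snapshot"):
            link_records(labels, preds, demos, threshold=0.5, policy="snapshot")

    def test_duplicate_demographics_error_lists_patient_ids(self):
        labels = pd.DataFrame(
            {"patient_id": ["p0"], "label_date": [dt.date(2022, 3, 4)], "label": [1]}
        )
        preds = pd.DataFrame([pred_row("p0", 0.1)])
        demos = pd.DataFrame([demo_row("p0"), demo_row("p0")])
        with pytest.raises(DuplicateDemographicsError, match="p0"):
            link_records(labels, preds, demos, threshold=0.5)

    def test_flag_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        n = 60
        labels = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "label_date": [dt.date(2022, 3, 1)] * n,
                "label": rng.integers(0, 2, n),
            }
        )
        preds = pd.DataFrame([pred_row(f"p{i}", float(rng.random())) for i in range(n)])
        demos = pd.DataFrame([demo_row(f"p{i}") for i in range(n)])
        flagged = [
            link_records(labels, preds, demos, threshold=t).records["flag"].sum()
            for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert flagged == sorted(flagged, reverse=True)


class TestAgeAndBin:
    @pytest.mark.parametrize(
        "dob,ref,age,bin_",
        [
            (dt.date(1942, 2, 11), dt.date(2022, 2, 11), 80, "(70, 80]"),
            (dt.date(1942, 3, 1), dt.date(2022, 2, 11), 79, "(70, 80]"),
            (dt.date(2007, 1, 1), dt.date(2022, 2, 11), 15, "(10, 20]"),
            (dt.date(1932, 2, 12), dt.date(2022, 2, 11), 89, "(80, 90]"),
        ],
    )
    def test_examples(self, dob, ref, age, bin_):
        assert age_and_bin(dob, ref) == (age, bin_)

    def test_reference_before_birth_errors(self):
        with pytest.raises(ValueError):
            age_and_bin(dt.date(2000, 1, 1), dt.date(1999, 12, 31))

    @given(
        dob_days=st.integers(0, 40000),
        extra_days=st.integers(0, 40000),
    )
    @settings(max_examples=100, deadline=None)
    def test_age_matches_day_count_oracle_and_bin_contains_age(self, dob_days, extra_days):
        dob = dt.date(1920, 1, 1) + dt.timedelta(days=dob_days)
        ref = dob + dt.timedelta(days=extra_days)
        age, bin_ = age_and_bin(dob, ref)
        # oracle: largest k such that dob shifted forward k years is <= ref
        k = 0
        while True:
            try:
                shifted = dob.replace(year=dob.year + k + 1)
            except ValueError:  # Feb 29
                shifted = dt.date(dob.year + k + 1, 3, 1)
            if shifted <= ref:
                k += 1
            else:
                break
        assert age == k
        lower = int(bin_.split(",")[0][1:])
        upper = int(bin_.split(",")[1][:-1])
        assert lower < age <= upper
        assert upper - lower == 10


class TestEnumerateSubgroups:
    def test_single_record_yields_four_subgroups(self):
        records = pd.DataFrame(
            [
                {
                    "patient_id": "p0",
                    "label_date": dt.date(2022, 3, 1),
                    "label": 1,
                    "score": 0.5,
                    "flag": 1,
                    "sex": "Female",
                    "ethnicity": "Hispanic or Latino",
                    "race": "Other",
                    "age_years": 45,
                    "age_bin": "(40, 50]",
                }
            ]
        )
        defs = enumerate_subgroups(AuditCohort(records=records))
        names = [d.display_name for d in defs]
        assert names == [
            "Sex: Female",
            "Age: (40, 50]",
            "Ethnicity: Hispanic or Latino, Race: Other",
            "Ethnicity: Hispanic or Latino, Race: Other, Sex: Female",
        ]

    def test_full_cross_counts(self):
        groups = []
        for sex in ("Female", "Male"):
            for eth, race in (
                ("Hispanic or Latino", "Other"),
                ("Not Hispanic or Latino", "White"),
            ):
                groups.append((1, 1, 1, 1, {"sex": sex, "ethnicity": eth, "race": race, "age_years": 45}))
        cohort = AuditCohort(records=make_records(groups))
        defs = enumerate_subgroups(cohort)
        by_axis = {}
        for d in defs:
            by_axis.setdefault(d.axis, []).append(d)
        assert len(by_axis["sex"]) == 2
        assert len(by_axis["age"]) == 1  # all age 45
        assert len(by_axis["ethnicity_race"]) == 2
        assert len(by_axis["ethnicity_race_sex"]) == 4

    def test_only_observed_permutations(self):
        groups = [
            (1, 0, 1, 1, {"sex": "Female", "ethnicity": "Hispanic or Latino", "race": "White"}),
            (1, 0, 1, 1, {"sex": "Male", "ethnicity": "Not Hispanic or Latino", "race": "Asian"}),
        ]
        cohort = AuditCohort(records=make_records(groups))
        names = [d.display_name for d in enumerate_subgroups(cohort)]
        assert "Ethnicity: Hispanic or Latino, Race: White, Sex: Male" not in names
        assert "Ethnicity: Hispanic or Latino, Race: White, Sex: Female" in names

    def test_partition_within_axis(self):
        groups = [
            (2, 1, 3, 4, {"sex": "Female", "age_years": 45}),
            (1, 2, 0, 5, {"sex": "Male", "age_years": 72}),
            (0, 1, 1, 2, {"sex": "Male", "age_years": 45, "ethnicity": "Unknown"}),
        ]
        cohort = AuditCohort(records=make_records(groups))
        defs = enumerate_subgroups(cohort)
        records = cohort.records
        for axis, attrs in (("sex", ["sex"]), ("age", ["age_bin"]), ("ethnicity_race", ["ethnicity", "race"])):
            axis_defs = [d for d in defs if d.axis == axis]
            total = sum(int(d.mask(records).sum()) for d in axis_defs)
            non_missing = int(
                (~records[attrs].isin(["Unknown"]).any(axis=1)).sum()
            )
            assert total == non_missing

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            enumerate_subgroups(AuditCohort(records=pd.DataFrame(columns=["sex"])))
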