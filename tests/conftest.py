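import datetime as dt

import pandas as pd
import pytest
from hypothesis import settings

from riskaudit import fixture_from_counts

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def primary_care_cohort():
    """338-record cohort matching the primary-care 2x2 (tp=25, fp=5, fn=43, tn=265), E=16.4."""
    return fixture_from_counts(25, 5, 43, 265, 16.4, 0.15)


@pytest.fixture(scope="session")
def hm_cohort():
    """225-record hospital-medicine cohort (tp=68, fp=17, fn=31, tn=109), E=65.2."""
    return fixture_from_counts(68, 17, 31, 109, 65.2, 0.25)


def make_records(groups):
    """Hand-built audit records.

    ``groups``: iterables of (tp, fp, fn, tn, demographics) where
    demographics is a dict with sex/ethnicity/race/age_years keys.
    Flagged records score 0.8, unflagged 0.05 (threshold 0.5).
    """
    rows = []
    i = 0
    for tp, fp, fn, tn, demo in groups:
        age = demo.get("age_years", 65)
        lower = ((age - 1) // 10) * 10
        base = {
            "sex": demo.get("sex", "Female"),
            "ethnicity": demo.get("ethnicity", "Not Hispanic or Latino"),
            "race": demo.get("race", "White"),
            "age_years": age,
            "age_bin": f"({lower}, {lower + 10}]",
        }
        for count, label, flag in ((tp, 1, 1), (fp, 0, 1), (fn, 1, 0), (tn, 0, 0)):
            for _ in range(count):
                rows.append(
                    {
                        "patient_id": f"p{i:05d}",
                        "label_date": dt.date(2022, 3, 1),
                        "label": label,
                        "score": 0.8 if flag else 0.05,
                        "flag": flag,
                        **base,
                    }
                )
                i += 1
    return pd.DataFrame(rows)
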