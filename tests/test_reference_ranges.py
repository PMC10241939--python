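"""The guideline MetS rule: conditions, thresholds, and the 3-of-5 count."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metsflow.errors import ConfigurationError, MissingDataError
from metsflow.reference_ranges import (
    CONDITIONS,
    IndicatorSpec,
    MetSCriteria,
    abnormal_state,
    diagnose_frame,
    diagnose_mets,
    evaluate_condition,
)

HEALTHY = {
    "sex": "male", "WC": 80.0, "FGLU": 5.0, "SBP": 115.0, "DBP": 70.0,
    "TG": 1.0, "HDL-C": 1.5,
}


def record(**overrides):
    rec = dict(HEALTHY)
    rec.update(overrides)
    return rec


@pytest.mark.parametrize(
    "overrides,condition,expected",
    [
        ({"sex": "male", "WC": 92.0}, "abdominal_obesity", True),
        ({"sex": "female", "WC": 85.0}, "abdominal_obesity", True),  # inclusive
        ({"sex": "female", "WC": 84.9}, "abdominal_obesity", False),
        ({"sex": "male", "WC": 89.9}, "abdominal_obesity", False),
        ({"TG": 1.70}, "high_tg", True),
        ({"TG": 1.69}, "high_tg", False),
        ({"HDL-C": 1.04}, "low_hdlc", True),
        ({"HDL-C": 1.05}, "low_hdlc", False),
        ({"FGLU": 6.1}, "hyperglycemia", True),
        ({"FGLU": 6.0}, "hyperglycemia", False),
        ({"FGLU": 6.0, "PG": 7.8}, "hyperglycemia", True),
        ({"SBP": 130.0}, "hypertension", True),
        ({"SBP": 129.0, "DBP": 85.0}, "hypertension", True),
        ({"SBP": 129.0, "DBP": 84.0}, "hypertension", False),
    ],
)
def test_condition_thresholds_inclusive(overrides, condition, expected):
    assert evaluate_condition(record(**overrides), condition) is expected


def test_history_flags_satisfy_conditions():
    rec = record(diagnosed_hypertension=True)
    assert evaluate_condition(rec, "hypertension") is True
    off = MetSCriteria(use_history_flags=False)
    assert evaluate_condition(rec, "hypertension", off) is False
    rec = record(diagnosed_diabetes=True)
    assert evaluate_condition(rec, "hyperglycemia") is True


def test_hypertension_and_reading():
    both = MetSCriteria(hypertension_or=False)
    assert evaluate_condition(record(SBP=135.0, DBP=80.0), "hypertension", both) is False
    assert evaluate_condition(record(SBP=135.0, DBP=90.0), "hypertension", both) is True


def test_missing_indicator_is_named():
    rec = record()
    del rec["TG"]
    with pytest.raises(MissingDataError, match="TG"):
        evaluate_condition(rec, "high_tg")
    with pytest.raises(ConfigurationError):
        evaluate_condition(rec, "not_a_condition")


@pytest.mark.parametrize(
    "overrides,expected",
    [
        # three conditions met (obesity, glycemia, TG)
        ({"WC": 92.0, "FGLU": 6.5, "TG": 1.9, "HDL-C": 1.20, "SBP": 120.0,
          "DBP": 80.0}, (1, 3)),
        # exactly two met
        ({"WC": 92.0, "TG": 1.9}, (0, 2)),
        # all five
        ({"WC": 95.0, "FGLU": 7.0, "SBP": 140.0, "TG": 2.5, "HDL-C": 0.9},
         (1, 5)),
        ({}, (0, 0)),
    ],
)
def test_diagnose_counts(overrides, expected):
    label, n = diagnose_mets(record(**overrides))
    assert (label, n) == expected


def test_diagnose_undecidable_raises():
    rec = record(WC=92.0, TG=1.9)  # 2 met
    del rec["FGLU"]  # unknown could reach 3
    with pytest.raises(MissingDataError):
        diagnose_mets(rec)
    # decidable despite a missing value: already at 3 without FGLU
    rec = record(WC=92.0, TG=1.9, HDL_C=0.9)
    rec["HDL-C"] = 0.9
    del rec["FGLU"]
    assert diagnose_mets(rec)[0] == 1


def _oracle_n_met(rec):
    """Independent hand-coded rule table."""
    n = 0
    n += rec["WC"] >= (90.0 if rec["sex"] == "male" else 85.0)
    n += rec["FGLU"] >= 6.1
    n += rec["SBP"] >= 130.0 or rec["DBP"] >= 85.0
    n += rec["TG"] >= 1.70
    n += rec["HDL-C"] <= 1.04
    return int(n)


def test_boundary_grid_matches_rule_table():
    """All 3^5 combinations of below/at/above each condition's threshold."""
    eps = 1e-6
    male_levels = {
        "abdominal_obesity": [("WC", 90.0 + d) for d in (-eps, 0.0, eps)],
        "hyperglycemia": [("FGLU", 6.1 + d) for d in (-eps, 0.0, eps)],
        "hypertension": [("SBP", 130.0 + d) for d in (-eps, 0.0, eps)],
        "high_tg": [("TG", 1.70 + d) for d in (-eps, 0.0, eps)],
        # deficit-type: risk side is below the limit
        "low_hdlc": [("HDL-C", 1.04 + d) for d in (eps, 0.0, -eps)],
    }
    for combo in itertools.product(*(male_levels[c] for c in CONDITIONS)):
        rec = {"sex": "male", "DBP": 70.0}
        rec.update(dict(combo))
        label, n = diagnose_mets(rec)
        assert n == _oracle_n_met(rec)
        assert label == int(n >= 3)


@given(
    wc=st.floats(60, 120), fglu=st.floats(3, 10), sbp=st.floats(90, 180),
    dbp=st.floats(50, 110), tg=st.floats(0.3, 6), hdl=st.floats(0.5, 2.5),
    bump=st.floats(0.1, 30),
    target=st.sampled_from(["WC", "FGLU", "SBP", "TG"]),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_raising_risk_indicator_is_monotone(wc, fglu, sbp, dbp, tg, hdl, bump, target):
    rec = {"sex": "male", "WC": wc, "FGLU": fglu, "SBP": sbp, "DBP": dbp,
           "TG": tg, "HDL-C": hdl}
    _, n_before = diagnose_mets(rec)
    rec[target] = rec[target] + bump
    _, n_after = diagnose_mets(rec)
    assert n_after >= n_before
    # lowering HDL-C (deficit risk) is likewise monotone
    rec["HDL-C"] = rec["HDL-C"] - 1.0
    _, n_lower_hdl = diagnose_mets(rec)
    assert n_lower_hdl >= n_after


def test_diagnose_frame_matches_scalar():
    rng = np.random.default_rng(5)
    n = 200
    df = pd.DataFrame({
        "sex": rng.choice(["male", "female"], n),
        "WC": rng.uniform(60, 110, n),
        "FGLU": rng.uniform(3, 9, n),
        "SBP": rng.uniform(90, 170, n),
        "DBP": rng.uniform(50, 110, n),
        "TG": rng.uniform(0.3, 4, n),
        "HDL-C": rng.uniform(0.5, 2.5, n),
    })
    out = diagnose_frame(df)
    for i, row in df.iterrows():
        label, n_met = diagnose_mets(row)
        assert out.loc[i, "mets"] == label
        assert out.loc[i, "n_conditions_met"] == n_met


def test_diagnose_frame_rejects_missing():
    df = pd.DataFrame([dict(HEALTHY)])
    df.loc[0, "TG"] = np.nan
    with pytest.raises(MissingDataError, match="TG"):
        diagnose_frame(df)


def test_spec_validation():
    with pytest.raises(ConfigurationError):
        IndicatorSpec(name="X", units="u", lower=5.0, upper=1.0)
    with pytest.raises(ConfigurationError):
        IndicatorSpec(name="X", units="u")  # no limit at all
    with pytest.raises(ConfigurationError):
        IndicatorSpec(name="X", units="u", upper=1.0, scale_max=0.0)
    with pytest.raises(ConfigurationError):
        MetSCriteria(min_conditions=0)


def test_abnormal_state_sex_specific(registry):
    wc = registry["WC"]
    assert abnormal_state(90.0, wc, "male")
    assert not abnormal_state(89.9, wc, "male")
    assert abnormal_state(85.0, wc, "female")
    hdl = registry["HDL-C"]
    assert abnormal_state(1.04, hdl)
    assert not abnormal_state(1.05, hdl)
    bmi = registry["BMI"]  # strict limit
    assert not abnormal_state(24.0, bmi)
    assert abnormal_state(24.01, bmi)
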