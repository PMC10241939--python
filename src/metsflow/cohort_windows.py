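"""Construction of 5-year analysis windows.

A window is four consecutive exam years in which the subject is MetS-free
plus the immediately following year, whose MetS diagnosis is the prediction
label (``ms_result``). Subjects without five consecutive years, or whose
candidate input years contain a MetS-positive exam, contribute nothing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import MetsflowError
from .reference_ranges import MetSCriteria, diagnose_frame
from .synthetic_cohort import INDICATORS

__all__ = ["AGE_GROUPS", "assign_age_group", "age_group_series", "build_windows"]

#: Age-stratum labels used throughout the stratified analyses.
AGE_GROUPS = ("18-44", "45-59", ">=60")

N_INPUT_YEARS = 4


def assign_age_group(age: float) -> str:
    """Stratum for an age at the label year: 18-44, 45-59, >=60."""
    if age < 18:
        raise MetsflowError(f"age {age} below the study's 18-year inclusion floor")
    if age <= 44:
        return AGE_GROUPS[0]
    if age <= 59:
        return AGE_GROUPS[1]
    return AGE_GROUPS[2]


def age_group_series(ages: pd.Series) -> pd.Series:
    """Vectorized :func:`assign_age_group`."""
    if (ages < 18).any():
        raise MetsflowError("ages below 18 present")
    return pd.Series(
        pd.cut(
            ages,
            bins=[18, 44, 59, np.inf],
            labels=list(AGE_GROUPS),
            include_lowest=True,
        ).astype(str),
        index=ages.index,
        name="age_group",
    )


def build_windows(
    cohort: pd.DataFrame,
    criteria: MetSCriteria | None = None,
    mode: str = "first",
    min_label_age: float = 18.0,
    indicators: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Build window samples from a cleaned cohort.

    Parameters
    ----------
    cohort : DataFrame
        Wide person-year table (``subject_id, sex, age, year`` + indicators),
        cleaned and imputed: the MetS-rule indicators must be non-missing.
    criteria : MetSCriteria, optional
        Diagnostic rule applied to every person-year.
    mode : {"first", "all"}
        ``"first"`` keeps one window per subject (the earliest eligible),
        keeping samples independent for cross-validation; ``"all"`` emits
        every eligible (overlapping) window.
    min_label_age : float
        Inclusion floor on age at the label year.
    indicators : list of str, optional
        Indicator columns to carry into the window table (default: all
        known indicator columns present).

    Returns
    -------
    (windows, counts)
        ``windows``: one row per window with ``window_id, subject_id, sex,
        age_at_label, age_group, {indicator}_y1..y4, ms_result``.
        ``counts``: ``{"n_total", "n_positive", "n_negative"}``.
    """
    if mode not in ("first", "all"):
        raise MetsflowError(f"unknown window mode {mode!r}")
    if indicators is None:
        indicators = [c for c in cohort.columns if c in INDICATORS]

    df = cohort.sort_values(["subject_id", "year"], kind="stable").reset_index(drop=True)
    labels = diagnose_frame(df, criteria)
    mets = labels["mets"].to_numpy()

    sid = df["subject_id"].to_numpy()
    year = df["year"].to_numpy(float)
    age = df["age"].to_numpy(float)
    n = len(df)
    span = N_INPUT_YEARS  # window start p uses rows p .. p+4

    if n < span + 1:
        empty = _empty_windows(indicators)
        return empty, {"n_total": 0, "n_positive": 0, "n_negative": 0}

    # chain[k]: row k+1 is the same subject's next consecutive year
    chain = (sid[1:] == sid[:-1]) & (year[1:] == year[:-1] + 1)
    n_start = n - span
    valid = np.ones(n_start, dtype=bool)
    for off in range(span):
        valid &= chain[off : off + n_start]
    healthy = mets == 0
    for off in range(span):
        valid &= healthy[off : off + n_start]
    valid &= age[span:] >= min_label_age

    starts = np.flatnonzero(valid)
    if mode == "first" and len(starts):
        _, first_idx = np.unique(sid[starts], return_index=True)
        starts = starts[np.sort(first_idx)]

    ms = mets[starts + span].astype(int)
    columns = {
        "window_id": [f"{s}:{int(y)}" for s, y in zip(sid[starts], year[starts])],
        "subject_id": sid[starts],
        "sex": df["sex"].to_numpy()[starts],
        "age_at_label": age[starts + span],
    }
    columns["age_group"] = age_group_series(
        pd.Series(columns["age_at_label"])
    ).to_numpy()
    if "drift_group" in df.columns:
        columns["drift_group"] = df["drift_group"].to_numpy()[starts]
    for name in indicators:
        col = df[name].to_numpy(float)
        for k in range(span):
            columns[f"{name}_y{k + 1}"] = col[starts + k]
    columns["ms_result"] = ms
    out = pd.DataFrame(columns)

    counts = {
        "n_total": int(len(out)),
        "n_positive": int(ms.sum()),
        "n_negative": int(len(out) - ms.sum()),
    }
    return out, counts


def _empty_windows(indicators: list[str]) -> pd.DataFrame:
    cols = ["window_id", "subject_id", "sex", "age_at_label", "age_group"]
    cols += [f"{name}_y{k + 1}" for name in indicators for k in range(N_INPUT_YEARS)]
    cols += ["ms_result"]
    return pd.DataFrame(columns=cols)
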