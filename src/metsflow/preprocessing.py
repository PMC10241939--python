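"""Cohort cleaning: exclusion rules, outlier screening, imputation, derived
anthropometrics.

The protocol, applied in order by :func:`clean_cohort`:

1. drop subjects with more than 20 exam records;
2. drop records with age above 80; blank indicator values outside the
   physician plausibility bounds (cell-level, so a stray measurement does
   not break an otherwise usable 5-year run);
3. recompute WHR and BMI from raw anthropometrics where available;
4. drop features missing in more than 70% of records, then fill the rest —
   mean fill when the feature looks normally distributed, median fill when
   skewed, computed per sex by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .reference_ranges import IndicatorRegistry, default_registry

__all__ = [
    "CleaningReport",
    "exclude_heavy_users",
    "remove_outliers",
    "impute",
    "derive_anthropometrics",
    "clean_cohort",
]

_META_COLS = {"subject_id", "sex", "age", "year", "drift_group",
              "diagnosed_diabetes", "diagnosed_hypertension"}


@dataclass
class CleaningReport:
    """Accounting of what the cleaning chain did."""

    n_subjects_in: int = 0
    n_subjects_out: int = 0
    n_records_in: int = 0
    n_records_out: int = 0
    dropped_features: list = field(default_factory=list)  # (name, reason)
    imputed_counts: dict = field(default_factory=dict)
    imputation_method: dict = field(default_factory=dict)
    outlier_cells_blanked: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def exclude_heavy_users(
    cohort: pd.DataFrame, max_exams: int = 20
) -> tuple[pd.DataFrame, dict]:
    """Drop subjects with strictly more than ``max_exams`` exam records."""
    counts = cohort.groupby("subject_id", sort=False)["year"].size()
    keep = counts[counts <= max_exams].index
    out = cohort[cohort["subject_id"].isin(keep)].reset_index(drop=True)
    fragment = {
        "n_subjects_dropped_heavy_users": int((counts > max_exams).sum()),
    }
    return out, fragment


def remove_outliers(
    cohort: pd.DataFrame,
    registry: IndicatorRegistry | None = None,
    age_max: float = 80.0,
) -> tuple[pd.DataFrame, dict]:
    """Drop records with age strictly above ``age_max``; blank values outside
    the physician plausibility bounds.

    Out-of-plausibility values become missing rather than removing the whole
    record, preserving multi-year continuity for window construction.
    Indicators without plausibility bounds trigger a warning and pass
    through unfiltered.
    """
    registry = registry or default_registry()
    out = cohort[cohort["age"] <= age_max].reset_index(drop=True).copy()
    blanked: dict[str, int] = {}
    for spec in registry:
        if spec.name not in out.columns:
            continue
        if spec.plausible_low is None and spec.plausible_high is None:
            warnings.warn(
                f"indicator {spec.name!r} has no plausibility bounds; "
                "no outlier screening applied",
                stacklevel=2,
            )
            continue
        lo = spec.plausible_low if spec.plausible_low is not None else -np.inf
        hi = spec.plausible_high if spec.plausible_high is not None else np.inf
        values = out[spec.name]
        bad = values.notna() & ((values < lo) | (values > hi))
        if bad.any():
            out.loc[bad, spec.name] = np.nan
        blanked[spec.name] = int(bad.sum())
    fragment = {
        "n_records_dropped_age": int((cohort["age"] > age_max).sum()),
        "outlier_cells_blanked": blanked,
    }
    return out, fragment


def _looks_normal(values: np.ndarray, alpha: float, cap: int = 5000) -> bool:
    """Normal-vs-skewed call: Shapiro-Wilk on a capped subsample plus a
    |skewness| > 1 fallback for large samples where the test over-rejects."""
    values = values[np.isfinite(values)]
    if len(values) < 8:
        return abs(stats.skew(values)) <= 1.0 if len(values) >= 3 else True
    sample = values if len(values) <= cap else values[:: max(1, len(values) // cap)][:cap]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.shapiro(sample)
    if p >= alpha:
        return True
    # large-n Shapiro rejects tiny departures; treat near-symmetric as normal
    return abs(stats.skew(values)) <= 1.0


def impute(
    cohort: pd.DataFrame,
    features: list[str] | None = None,
    drop_threshold: float = 0.70,
    alpha: float = 0.05,
    per_sex: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Drop heavily missing features, fill the remainder.

    A feature missing in strictly more than ``drop_threshold`` of records is
    dropped. Otherwise missing cells are filled with the mean when the
    observed distribution is compatible with normality at level ``alpha``,
    else with the median — per sex when ``per_sex`` (sexes differ in level
    for most indicators).
    """
    out = cohort.copy()
    if features is None:
        features = [
            c for c in out.columns
            if c not in _META_COLS and pd.api.types.is_numeric_dtype(out[c])
        ]
    dropped: list[tuple[str, str]] = []
    imputed_counts: dict[str, int] = {}
    methods: dict[str, str] = {}
    for name in features:
        missing = out[name].isna()
        frac = float(missing.mean()) if len(out) else 1.0
        if frac >= 1.0:
            out = out.drop(columns=[name])
            dropped.append((name, "100% missing"))
            continue
        if frac > drop_threshold:
            out = out.drop(columns=[name])
            dropped.append((name, f"{frac:.0%} missing > {drop_threshold:.0%}"))
            continue
        if not missing.any():
            continue
        normal = _looks_normal(out[name].to_numpy(float), alpha)
        methods[name] = "mean" if normal else "median"
        imputed_counts[name] = int(missing.sum())
        if per_sex and "sex" in out.columns:
            grouped = out.groupby("sex")[name]
            fill = grouped.transform("mean" if normal else "median")
        else:
            fill = pd.Series(
                out[name].mean() if normal else out[name].median(), index=out.index
            )
        out[name] = out[name].fillna(fill)
    fragment = {
        "dropped_features": dropped,
        "imputed_counts": imputed_counts,
        "imputation_method": methods,
    }
    return out, fragment


def derive_anthropometrics(cohort: pd.DataFrame) -> pd.DataFrame:
    """Recompute WHR (= waist / hip) and BMI (= weight / height_m^2) from raw
    anthropometrics where present; otherwise pass existing columns through.

    Nonpositive denominators yield missing values with a warning.
    """
    out = cohort.copy()
    if "WC" in out.columns and "hip" in out.columns:
        hip = out["hip"]
        bad = hip.notna() & (hip <= 0)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} records with nonpositive hip circumference; "
                "WHR set missing",
                stacklevel=2,
            )
        out["WHR"] = np.where(hip > 0, out["WC"] / hip, np.nan)
    if "weight" in out.columns and "height" in out.columns:
        height_m = out["height"] / 100.0
        bad = height_m.notna() & (height_m <= 0)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} records with nonpositive height; BMI set missing",
                stacklevel=2,
            )
        out["BMI"] = np.where(height_m > 0, out["weight"] / height_m**2, np.nan)
    return out


def clean_cohort(
    cohort: pd.DataFrame,
    registry: IndicatorRegistry | None = None,
    max_exams: int = 20,
    age_max: float = 80.0,
    drop_threshold: float = 0.70,
    alpha: float = 0.05,
    per_sex: bool = True,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Run the full cleaning chain and return the cleaned table plus report."""
    registry = registry or default_registry()
    report = CleaningReport(
        n_subjects_in=int(cohort["subject_id"].nunique()),
        n_records_in=int(len(cohort)),
    )
    out, frag1 = exclude_heavy_users(cohort, max_exams=max_exams)
    out, frag2 = remove_outliers(out, registry, age_max=age_max)
    out = derive_anthropometrics(out)
    out, frag3 = impute(
        out, drop_threshold=drop_threshold, alpha=alpha, per_sex=per_sex
    )
    report.outlier_cells_blanked = frag2["outlier_cells_blanked"]
    report.dropped_features = frag3["dropped_features"]
    report.imputed_counts = frag3["imputed_counts"]
    report.imputation_method = frag3["imputation_method"]
    report.n_subjects_out = int(out["subject_id"].nunique())
    report.n_records_out = int(len(out))
    return out, report
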