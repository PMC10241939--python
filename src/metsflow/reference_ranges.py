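"""Clinical indicator registry and the metabolic-syndrome diagnostic rule.

The registry holds one :class:`IndicatorSpec` per continuous exam indicator:
its units, normal-range limits (optionally sex-specific), the direction in
which values become risky, physician plausibility bounds used for outlier
screening, and the scaling constant applied to the risk distance before the
sigmoid weight in :mod:`metsflow.temporal_features`.

MetS is diagnosed by the Chinese 2017 type-2-diabetes guideline rule: a
person-year is positive when it meets at least three of five conditions
(abdominal obesity, hyperglycemia, hypertension, elevated triglycerides, low
HDL cholesterol), with thresholds applied inclusively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, MissingDataError

__all__ = [
    "IndicatorSpec",
    "IndicatorRegistry",
    "MetSCriteria",
    "CONDITIONS",
    "evaluate_condition",
    "diagnose_mets",
    "diagnose_frame",
    "default_registry",
    "abnormal_state",
]

#: The five diagnostic conditions, in guideline order.
CONDITIONS = (
    "abdominal_obesity",
    "hyperglycemia",
    "hypertension",
    "high_tg",
    "low_hdlc",
)


def _is_missing(value) -> bool:
    if value is None:
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class IndicatorSpec:
    """Metadata for one clinical indicator.

    Parameters
    ----------
    name : str
        Indicator identifier, e.g. ``"TG"`` or ``"HDL-C"``.
    units : str
        Clinical unit string (mmol/L, cm, mmHg, ...).
    risk_direction : {"high", "low"}
        ``"high"`` when values above the upper limit are the risk state,
        ``"low"`` when values below the lower limit are (HDL-C).
    lower, upper : float, optional
        Normal-range limits. At least one must be present (possibly via
        ``sex_specific``); when both are present ``lower < upper``.
    inclusive : bool
        Whether abnormality at the limit itself counts (``>=`` / ``<=``,
        used for the guideline's MetS thresholds) or only strictly beyond.
    sex_specific : mapping, optional
        Per-sex override, e.g. ``{"male": {"upper": 90.0}}``.
    plausible_low, plausible_high : float, optional
        Physician plausibility bounds; values outside are measurement
        errors, not physiology, and are blanked during cleaning.
    scale_max : float, optional
        Positive constant dividing the raw risk distance ``x`` before the
        sigmoid weight. Usually fitted on a cohort and frozen.
    """

    name: str
    units: str
    risk_direction: str = "high"
    lower: float | None = None
    upper: float | None = None
    inclusive: bool = False
    sex_specific: Mapping[str, Mapping[str, float]] | None = None
    plausible_low: float | None = None
    plausible_high: float | None = None
    scale_max: float | None = None

    def __post_init__(self):
        if self.risk_direction not in ("high", "low"):
            raise ConfigurationError(
                f"{self.name}: risk_direction must be 'high' or 'low', "
                f"got {self.risk_direction!r}"
            )
        has_limit = self.lower is not None or self.upper is not None
        if self.sex_specific:
            for limits in self.sex_specific.values():
                if "lower" in limits or "upper" in limits:
                    has_limit = True
        if not has_limit:
            raise ConfigurationError(f"{self.name}: no normal-range limit given")
        if self.lower is not None and self.upper is not None:
            if not self.lower < self.upper:
                raise ConfigurationError(
                    f"{self.name}: lower limit {self.lower} must be below "
                    f"upper limit {self.upper}"
                )
        if self.scale_max is not None and not self.scale_max > 0:
            raise ConfigurationError(f"{self.name}: scale_max must be > 0")

    def limits(self, sex: str | None = None) -> tuple[float | None, float | None]:
        """Return ``(lower, upper)`` for the given sex."""
        lower, upper = self.lower, self.upper
        if self.sex_specific and sex is not None:
            override = self.sex_specific.get(sex, {})
            lower = override.get("lower", lower)
            upper = override.get("upper", upper)
        return lower, upper

    def risk_limit(self, sex: str | None = None) -> float:
        """The limit on the risky side: upper for high-risk, lower for low-risk."""
        lower, upper = self.limits(sex)
        limit = upper if self.risk_direction == "high" else lower
        if limit is None:
            raise ConfigurationError(
                f"{self.name}: no {'upper' if self.risk_direction == 'high' else 'lower'} "
                f"limit configured (sex={sex!r})"
            )
        return limit


class IndicatorRegistry:
    """Ordered collection of :class:`IndicatorSpec`, keyed by name."""

    def __init__(self, specs: list[IndicatorSpec]):
        self._specs = {s.name: s for s in specs}
        if len(self._specs) != len(specs):
            raise ConfigurationError("duplicate indicator names in registry")

    def __getitem__(self, name: str) -> IndicatorSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise ConfigurationError(f"unknown indicator {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __iter__(self) -> Iterator[IndicatorSpec]:
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def with_scale_max(self, scale_max: Mapping[str, float]) -> "IndicatorRegistry":
        """Return a copy with ``scale_max`` set for the named indicators."""
        specs = [
            replace(s, scale_max=float(scale_max[s.name]))
            if s.name in scale_max
            else s
            for s in self
        ]
        return IndicatorRegistry(specs)

    @classmethod
    def from_yaml(cls, path) -> "IndicatorRegistry":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: Mapping) -> "IndicatorRegistry":
        specs = []
        for row in payload["indicators"]:
            row = dict(row)
            specs.append(IndicatorSpec(**row))
        return cls(specs)


def default_registry() -> IndicatorRegistry:
    """The registry shipped with the package (see ``data/reference_ranges.yaml``)."""
    text = (
        resources.files("metsflow")
        .joinpath("data/reference_ranges.yaml")
        .read_text()
    )
    return IndicatorRegistry._from_payload(yaml.safe_load(text))


def abnormal_state(values, spec: IndicatorSpec, sex: str | None = None):
    """Whether values are in the risk-direction abnormal state.

    High-risk indicators are abnormal above the upper limit, deficit-type
    (HDL-C) below the lower limit; ``spec.inclusive`` decides whether the
    boundary itself counts (the guideline thresholds are inclusive, the
    generic reference limits are strict).

    Works on scalars or array-likes; returns the matching boolean shape.
    """
    limit = spec.risk_limit(sex)
    arr = np.asarray(values, dtype=float)
    if spec.risk_direction == "high":
        out = arr >= limit if spec.inclusive else arr > limit
    else:
        out = arr <= limit if spec.inclusive else arr < limit
    return bool(out) if np.isscalar(values) else out


@dataclass(frozen=True)
class MetSCriteria:
    """Thresholds of the guideline MetS rule (all inclusive).

    ``hypertension_or`` selects the reading of the blood-pressure clause:
    when True (default) hypertension is SBP >= 130 OR DBP >= 85 OR a
    diagnosed-hypertension history flag, the standard MetS convention.
    ``use_history_flags`` controls whether self-reported diagnosed diabetes /
    hypertension satisfy the corresponding condition when measurements are
    normal.
    """

    wc_threshold_male: float = 90.0
    wc_threshold_female: float = 85.0
    fglu_threshold: float = 6.1
    pg_threshold: float = 7.8
    sbp_threshold: float = 130.0
    dbp_threshold: float = 85.0
    tg_threshold: float = 1.70
    hdlc_threshold: float = 1.04
    min_conditions: int = 3
    hypertension_or: bool = True
    use_history_flags: bool = True

    def __post_init__(self):
        thresholds = (
            self.wc_threshold_male,
            self.wc_threshold_female,
            self.fglu_threshold,
            self.pg_threshold,
            self.sbp_threshold,
            self.dbp_threshold,
            self.tg_threshold,
            self.hdlc_threshold,
        )
        if any(t <= 0 for t in thresholds):
            raise ConfigurationError("all MetS thresholds must be strictly positive")
        if self.min_conditions not in range(1, 6):
            raise ConfigurationError("min_conditions must be in 1..5")


def _require(record: Mapping, key: str):
    value = record.get(key) if hasattr(record, "get") else record[key]
    if key not in record or _is_missing(value):
        raise MissingDataError(f"indicator {key!r} is missing from the record")
    return float(value)


def _history_flag(record: Mapping, key: str, criteria: MetSCriteria) -> bool:
    if not criteria.use_history_flags:
        return False
    if key not in record:
        return False
    value = record[key]
    return bool(value) and not _is_missing(value)


def evaluate_condition(
    record: Mapping,
    condition: str,
    criteria: MetSCriteria | None = None,
) -> bool:
    """Evaluate one of the five MetS conditions on a single person-year.

    ``record`` is any mapping (dict, :class:`pandas.Series`) with a ``sex``
    entry (``"male"``/``"female"``) and the indicator values the condition
    needs, in guideline units. Thresholds are inclusive.

    Raises
    ------
    MissingDataError
        If a required indicator is absent, naming the indicator.
    ConfigurationError
        If ``condition`` is not one of the five known conditions.
    """
    criteria = criteria or MetSCriteria()
    if condition == "abdominal_obesity":
        sex = record.get("sex") if hasattr(record, "get") else record["sex"]
        if sex not in ("male", "female"):
            raise MissingDataError("record needs sex in {'male','female'} for WC threshold")
        threshold = (
            criteria.wc_threshold_male if sex == "male" else criteria.wc_threshold_female
        )
        return _require(record, "WC") >= threshold
    if condition == "hyperglycemia":
        if _history_flag(record, "diagnosed_diabetes", criteria):
            return True
        # 2-h postprandial glucose is optional; checked only when present
        if "PG" in record and not _is_missing(record["PG"]):
            if float(record["PG"]) >= criteria.pg_threshold:
                return True
        return _require(record, "FGLU") >= criteria.fglu_threshold
    if condition == "hypertension":
        if _history_flag(record, "diagnosed_hypertension", criteria):
            return True
        sbp = _require(record, "SBP")
        dbp = _require(record, "DBP")
        high_sbp = sbp >= criteria.sbp_threshold
        high_dbp = dbp >= criteria.dbp_threshold
        return (high_sbp or high_dbp) if criteria.hypertension_or else (high_sbp and high_dbp)
    if condition == "high_tg":
        return _require(record, "TG") >= criteria.tg_threshold
    if condition == "low_hdlc":
        return _require(record, "HDL-C") <= criteria.hdlc_threshold
    raise ConfigurationError(f"unknown MetS condition {condition!r}")


def diagnose_mets(
    record: Mapping, criteria: MetSCriteria | None = None
) -> tuple[int, int]:
    """Apply the >= 3-of-5 rule to one person-year.

    Returns ``(label, n_conditions_met)``. Conditions that cannot be
    evaluated because of missing values are tolerated as long as the
    decision is still forced; otherwise a :class:`MissingDataError` is
    raised.
    """
    criteria = criteria or MetSCriteria()
    n_met = 0
    n_unknown = 0
    for condition in CONDITIONS:
        try:
            n_met += int(evaluate_condition(record, condition, criteria))
        except MissingDataError:
            n_unknown += 1
    if n_met >= criteria.min_conditions:
        return 1, n_met
    if n_met + n_unknown < criteria.min_conditions:
        return 0, n_met
    raise MissingDataError(
        f"only {5 - n_unknown} of 5 conditions evaluable ({n_met} met): "
        "cannot decide the MetS label"
    )


def diagnose_frame(
    df: pd.DataFrame, criteria: MetSCriteria | None = None
) -> pd.DataFrame:
    """Vectorized diagnosis over a wide table of person-years.

    ``df`` needs columns ``sex``, ``WC``, ``FGLU``, ``SBP``, ``DBP``, ``TG``,
    ``HDL-C`` (plus optional ``PG`` and history-flag columns). Returns a
    DataFrame with ``n_conditions_met`` and ``mets`` aligned to ``df.index``.

    Missing values in any required column raise: labeling must run on
    cleaned, imputed data.
    """
    criteria = criteria or MetSCriteria()
    required = ["sex", "WC", "FGLU", "SBP", "DBP", "TG", "HDL-C"]
    for col in required:
        if col not in df.columns:
            raise MissingDataError(f"indicator {col!r} is missing from the table")
        if df[col].isna().any():
            raise MissingDataError(
                f"indicator {col!r} has {int(df[col].isna().sum())} missing values; "
                "impute before labeling"
            )
    male = df["sex"].eq("male").to_numpy()
    wc_threshold = np.where(male, criteria.wc_threshold_male, criteria.wc_threshold_female)

    obesity = df["WC"].to_numpy(float) >= wc_threshold
    glycemia = df["FGLU"].to_numpy(float) >= criteria.fglu_threshold
    if "PG" in df.columns:
        glycemia |= df["PG"].to_numpy(float) >= criteria.pg_threshold
    if criteria.use_history_flags and "diagnosed_diabetes" in df.columns:
        glycemia |= df["diagnosed_diabetes"].fillna(False).astype(bool).to_numpy()
    high_sbp = df["SBP"].to_numpy(float) >= criteria.sbp_threshold
    high_dbp = df["DBP"].to_numpy(float) >= criteria.dbp_threshold
    pressure = (high_sbp | high_dbp) if criteria.hypertension_or else (high_sbp & high_dbp)
    if criteria.use_history_flags and "diagnosed_hypertension" in df.columns:
        pressure |= df["diagnosed_hypertension"].fillna(False).astype(bool).to_numpy()
    tg = df["TG"].to_numpy(float) >= criteria.tg_threshold
    hdl = df["HDL-C"].to_numpy(float) <= criteria.hdlc_threshold

    n_met = (
        obesity.astype(int) + glycemia.astype(int) + pressure.astype(int)
        + tg.astype(int) + hdl.astype(int)
    )
    return pd.DataFrame(
        {"n_conditions_met": n_met, "mets": (n_met >= criteria.min_conditions).astype(int)},
        index=df.index,
    )
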