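"""Stratified epidemiological analysis of abnormality flags.

Exposure is an abnormality flag — an original indicator beyond its normal
limit in the most recent input year, a DFF whose absolute value exceeds the
cohort mean of absolute values, or a positive most-recent DNF — and the
outcome is the following year's MetS label. Odds ratios come from 2x2
tables per (feature, sex, age-group) stratum with Woolf log-normal 95%
confidence intervals and a Haldane–Anscombe 0.5 continuity correction when
a single cell is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .cohort_windows import AGE_GROUPS
from .reference_ranges import IndicatorRegistry, abnormal_state
from .temporal_features import flag_abnormal_dff, flag_abnormal_dnf

__all__ = [
    "TwoByTwo",
    "ORResult",
    "flag_abnormal_original",
    "add_abnormal_flags",
    "odds_ratio",
    "stratified_or_table",
    "prevalence_given_state",
    "prevalence_table",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure x outcome counts: a/b exposed cases/non-cases, c/d unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConfigurationError("2x2 counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_flags(cls, exposed, outcome) -> "TwoByTwo":
        exposed = np.asarray(exposed, dtype=bool)
        outcome = np.asarray(outcome, dtype=bool)
        return cls(
            a=int((exposed & outcome).sum()),
            b=int((exposed & ~outcome).sum()),
            c=int((~exposed & outcome).sum()),
            d=int((~exposed & ~outcome).sum()),
        )


@dataclass(frozen=True)
class ORResult:
    or_value: float
    ci_low: float
    ci_high: float
    counts: TwoByTwo
    corrected: bool = False
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.or_value)


def flag_abnormal_original(values, spec, sex=None):
    """Original-feature abnormality: value beyond the risk-direction limit.

    The guideline MetS thresholds are inclusive; generic reference limits
    use the strict "exceeds" reading (``spec.inclusive`` decides).
    """
    return abnormal_state(values, spec, sex)


def odds_ratio(t: TwoByTwo, alpha: float = 0.05) -> ORResult:
    """Cross-product odds ratio with Woolf log-normal CI.

    A single zero cell gets the Haldane–Anscombe 0.5 correction on all four
    cells (flagged ``corrected``); two or more zero cells leave the OR
    undefined and the result missing with a reason.
    """
    cells = [t.a, t.b, t.c, t.d]
    n_zero = sum(c == 0 for c in cells)
    if n_zero >= 2:
        return ORResult(
            math.nan, math.nan, math.nan, counts=t,
            reason=f"{n_zero} zero cells: odds ratio undefined",
        )
    corrected = n_zero == 1
    a, b, c, d = ((x + 0.5 for x in cells) if corrected else cells)
    or_value = (a * d) / (b * c)
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ORResult(
        or_value=or_value,
        ci_low=or_value * math.exp(-z * se),
        ci_high=or_value * math.exp(z * se),
        counts=t,
        corrected=corrected,
    )


def add_abnormal_flags(
    features: pd.DataFrame,
    registry: IndicatorRegistry,
    per_sex: bool = False,
) -> pd.DataFrame:
    """Append abnormality flag columns to a feature matrix.

    Per indicator present: ``{IND}_y4_abn`` (original value in the most
    recent input year beyond its limit), ``{IND}_DFF_abn`` (|DFF| above the
    cohort mean of |DFF|; within-sex means when ``per_sex``) and
    ``{IND}_DNF_abn`` (most-recent-interval DNF strictly positive).
    """
    out = features.copy()
    sexes = out["sex"].to_numpy() if "sex" in out.columns else None
    for spec in registry:
        name = spec.name
        y4 = f"{name}_y4"
        if y4 in out.columns:
            if spec.sex_specific:
                if sexes is None:
                    raise ConfigurationError(
                        f"{name}: sex-specific limits need a sex column"
                    )
                flags = np.array(
                    [abnormal_state(v, spec, s) for v, s in zip(out[y4], sexes)]
                )
            else:
                flags = abnormal_state(out[y4].to_numpy(float), spec)
            out[f"{name}_y4_abn"] = flags
        dff = f"{name}_DFF"
        if dff in out.columns:
            g = out[dff].to_numpy(float)
            if per_sex and sexes is not None:
                flags = np.zeros(len(out), dtype=bool)
                for s in np.unique(sexes):
                    mask = sexes == s
                    flags[mask] = flag_abnormal_dff(g[mask])
                out[f"{name}_DFF_abn"] = flags
            else:
                out[f"{name}_DFF_abn"] = flag_abnormal_dff(g)
        dnf3 = f"{name}_DNF3"
        if dnf3 in out.columns:
            out[f"{name}_DNF_abn"] = flag_abnormal_dnf(out[dnf3].to_numpy(float))
    return out


def stratified_or_table(
    features: pd.DataFrame,
    flags: dict[str, str] | None = None,
    outcome: str = "ms_result",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Odds ratios per (feature, sex, age group) stratum.

    ``flags`` maps a display feature name to its boolean flag column;
    default: every ``*_y4_abn`` and ``*_DFF_abn`` column present. Empty
    strata are emitted as missing rows.
    """
    if flags is None:
        flags = {
            col.removesuffix("_abn"): col
            for col in features.columns
            if col.endswith("_y4_abn") or col.endswith("_DFF_abn")
        }
    for col in ("sex", "age_group", outcome):
        if col not in features.columns:
            raise ConfigurationError(f"feature table lacks required column {col!r}")
    rows = []
    for feature_name, flag_col in flags.items():
        for sex in ("male", "female"):
            for age_group in AGE_GROUPS:
                stratum = features[
                    (features["sex"] == sex) & (features["age_group"] == age_group)
                ]
                base = {
                    "feature": feature_name, "sex": sex, "age_group": age_group,
                }
                if len(stratum) == 0:
                    rows.append(
                        {**base, "a": 0, "b": 0, "c": 0, "d": 0,
                         "or": math.nan, "ci_low": math.nan, "ci_high": math.nan,
                         "corrected": False, "note": "empty stratum"}
                    )
                    continue
                t = TwoByTwo.from_flags(
                    stratum[flag_col].to_numpy(bool),
                    stratum[outcome].to_numpy(int) == 1,
                )
                res = odds_ratio(t, alpha=alpha)
                rows.append(
                    {**base, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                     "or": res.or_value, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "corrected": res.corrected,
                     "note": res.reason or ""}
                )
    return pd.DataFrame(rows)


def prevalence_given_state(
    features: pd.DataFrame, flag_col: str, outcome: str = "ms_result"
) -> float:
    """P(MetS in the label year | flag abnormal); NaN when nothing is flagged."""
    flagged = features[features[flag_col].astype(bool)]
    if len(flagged) == 0:
        return math.nan
    return float((flagged[outcome] == 1).mean())


def prevalence_table(
    features: pd.DataFrame, outcome: str = "ms_result"
) -> pd.DataFrame:
    """Paired abnormal-state prevalences, DFF vs DNF, per indicator."""
    names = sorted(
        col.removesuffix("_DFF_abn")
        for col in features.columns
        if col.endswith("_DFF_abn")
    )
    rows = []
    for name in names:
        row = {"feature": name}
        row["prevalence_dff_abnormal"] = prevalence_given_state(
            features, f"{name}_DFF_abn", outcome
        )
        dnf_col = f"{name}_DNF_abn"
        row["prevalence_dnf_abnormal"] = (
            prevalence_given_state(features, dnf_col, outcome)
            if dnf_col in features.columns
            else math.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
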