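"""Temporal feature constructions over 4-year indicator trajectories.

Three families of derived features describe how an indicator moved across
the four input years of a window:

* **DNF** (differential numerical feature): the raw year-to-year change,
  ``I_curr - I_prev``, one per interval (y1->y2, y2->y3, y3->y4).
* **DSF** (differential state feature): the change in the indicator's
  normal/abnormal state between consecutive years, in {-1, 0, +1}.
* **DFF** (differential fluctuant feature): each interval's DNF is weighted
  by a sigmoid of the signed, scaled distance of the value from the
  indicator's normal limit —

      S(x) = 1 / (1 + exp(-a * x)),    F = DNF * S(x)

  so a given change counts more when it happens near or beyond the limit —
  and the three weighted terms are combined with geometric decay weights
  that favour recent intervals:

      G = b^3 * F_1 + b^2 * F_2 + b * F_3

  with F_1 the oldest interval. Defaults a = 50 (with x scaled to roughly
  [-1, 1]) and b = 0.6.

For deficit-type indicators (HDL-C) the risk distance is reflected,
``x = limit - value``, so clinically worsening values still receive weight
above 0.5; without the reflection the sigmoid would down-weight exactly the
risky HDL-C changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, MissingDataError
from .reference_ranges import IndicatorRegistry, IndicatorSpec, abnormal_state
from .cohort_windows import N_INPUT_YEARS

__all__ = [
    "DeltaTerm",
    "DFFValue",
    "compute_dnf",
    "sigmoid_weight",
    "scale_x",
    "compute_dff",
    "compute_dsf",
    "flag_abnormal_dnf",
    "flag_abnormal_dff",
    "fit_scale_max",
    "build_feature_matrix",
    "feature_groups",
    "FEATURE_SETS",
]

FEATURE_SETS = ("original", "dnf", "dsf", "dff")

_INTERVALS = ("y1->y2", "y2->y3", "y3->y4")

# open-interval clamp: the sigmoid weight must stay strictly inside (0, 1)
_EPS = 1e-15


@dataclass(frozen=True)
class DeltaTerm:
    """One interval's contribution to a DFF."""

    indicator: str
    interval: str
    i_prev: float
    i_curr: float
    dnf: float
    x: float          # scaled risk distance fed to the sigmoid
    s: float          # sigmoid weight, strictly in (0, 1)
    f: float          # dnf * s


@dataclass(frozen=True)
class DFFValue:
    """Combined differential fluctuant feature for one indicator/window."""

    indicator: str
    b: float
    g: float
    terms: tuple[DeltaTerm, DeltaTerm, DeltaTerm]


def compute_dnf(i_prev: float, i_curr: float) -> float:
    """Year-to-year numerical difference: current minus past value."""
    return i_curr - i_prev


def sigmoid_weight(x_scaled, a: float = 50.0):
    """Sigmoid risk weight ``1 / (1 + exp(-a x))``.

    Centered at (0, 0.5): a value exactly at the normal limit gets weight
    one half. Strictly increasing in ``x_scaled``; extreme arguments are
    clamped into the open interval (0, 1) instead of overflowing.
    """
    if not a > 0:
        raise ConfigurationError(f"sigmoid steepness a must be > 0, got {a}")
    out = expit(a * np.asarray(x_scaled, dtype=float))
    out = np.clip(out, _EPS, 1.0 - _EPS)
    return float(out) if np.isscalar(x_scaled) else out


def _raw_risk_distance(value, spec: IndicatorSpec, sex: str | None = None):
    limit = spec.risk_limit(sex)
    if spec.risk_direction == "high":
        return np.asarray(value, dtype=float) - limit
    return limit - np.asarray(value, dtype=float)


def scale_x(value: float, spec: IndicatorSpec, sex: str | None = None) -> float:
    """Signed, scaled distance of a value from the indicator's risk limit.

    Positive on the risky side of the limit regardless of risk direction;
    divided by ``spec.scale_max`` so different indicators share a common
    scale before the sigmoid.
    """
    if spec.scale_max is None:
        raise ConfigurationError(
            f"{spec.name}: scale_max not set; fit it on a cohort "
            "(fit_scale_max) or configure a constant"
        )
    raw = _raw_risk_distance(value, spec, sex)
    scaled = raw / spec.scale_max
    return float(scaled) if np.isscalar(value) else scaled


def compute_dff(
    values: Sequence[float],
    spec: IndicatorSpec,
    a: float = 50.0,
    b: float = 0.6,
    sex: str | None = None,
    x_at: str = "end",
    renormalize: bool = False,
) -> DFFValue:
    """Differential fluctuant feature from four consecutive annual values.

    ``x_at`` selects where each interval's risk distance is evaluated: at
    the interval's later year (``"end"``, default — the "current" value) or
    at the interval midpoint (``"mid"``). ``renormalize`` divides the decay
    weights by their sum ``b^3 + b^2 + b`` so they add to one.
    """
    values = [float(v) for v in values]
    if len(values) != N_INPUT_YEARS:
        raise ConfigurationError(f"need {N_INPUT_YEARS} annual values, got {len(values)}")
    if any(np.isnan(values)):
        raise MissingDataError(f"{spec.name}: missing annual value in DFF input")
    weights = _decay_weights(b, renormalize)
    terms = []
    g = 0.0
    for k in range(3):
        prev, curr = values[k], values[k + 1]
        dnf = compute_dnf(prev, curr)
        at = curr if x_at == "end" else 0.5 * (prev + curr)
        x = scale_x(at, spec, sex)
        s = sigmoid_weight(x, a)
        f = dnf * s
        g += weights[k] * f
        terms.append(
            DeltaTerm(
                indicator=spec.name, interval=_INTERVALS[k],
                i_prev=prev, i_curr=curr, dnf=dnf, x=x, s=s, f=f,
            )
        )
    return DFFValue(indicator=spec.name, b=b, g=g, terms=tuple(terms))


def _decay_weights(b: float, renormalize: bool) -> np.ndarray:
    if not 0 < b < 1:
        raise ConfigurationError(f"decay parameter b must be in (0, 1), got {b}")
    w = np.array([b**3, b**2, b])
    if renormalize:
        w = w / w.sum()
    return w


def compute_dsf(
    value_prev: float, value_curr: float, spec: IndicatorSpec, sex: str | None = None
) -> int:
    """State difference: abnormal(curr) - abnormal(prev), in {-1, 0, +1}."""
    return int(abnormal_state(value_curr, spec, sex)) - int(
        abnormal_state(value_prev, spec, sex)
    )


def flag_abnormal_dnf(dnf) -> bool | np.ndarray:
    """A DNF is abnormal when strictly positive (the indicator rose)."""
    arr = np.asarray(dnf, dtype=float) > 0
    return bool(arr) if np.isscalar(dnf) else arr


def flag_abnormal_dff(g_values) -> np.ndarray:
    """Abnormal DFFs: |g| strictly above the population mean of |g|."""
    arr = np.abs(np.asarray(g_values, dtype=float))
    if arr.size == 0:
        raise ConfigurationError("empty DFF population")
    return arr > arr.mean()


# ---------------------------------------------------------------------------
# windows -> feature matrix

def _year_block(windows: pd.DataFrame, name: str) -> np.ndarray:
    cols = [f"{name}_y{k + 1}" for k in range(N_INPUT_YEARS)]
    missing = [c for c in cols if c not in windows.columns]
    if missing:
        raise MissingDataError(f"window table lacks columns {missing}")
    return windows[cols].to_numpy(float)


def _per_row_limit(windows: pd.DataFrame, spec: IndicatorSpec) -> np.ndarray:
    sexes = windows["sex"].to_numpy()
    if spec.sex_specific:
        return np.array([spec.risk_limit(s) for s in sexes], dtype=float)
    return np.full(len(windows), spec.risk_limit(), dtype=float)


def _raw_x_matrix(
    windows: pd.DataFrame, spec: IndicatorSpec, x_at: str
) -> np.ndarray:
    """Raw (unscaled) risk distances, one column per interval."""
    v = _year_block(windows, spec.name)
    at = v[:, 1:] if x_at == "end" else 0.5 * (v[:, 1:] + v[:, :-1])
    limit = _per_row_limit(windows, spec)[:, None]
    return (at - limit) if spec.risk_direction == "high" else (limit - at)


def fit_scale_max(
    windows: pd.DataFrame,
    registry: IndicatorRegistry,
    indicators: Sequence[str] | None = None,
    x_at: str = "end",
) -> dict[str, float]:
    """Per-indicator scaling constants: max |raw risk distance| over the cohort.

    Fit once on the training windows and frozen into the registry so the
    feature transform is a pure function at predict time.
    """
    if indicators is None:
        indicators = [s.name for s in registry if f"{s.name}_y1" in windows.columns]
    scales = {}
    for name in indicators:
        raw = _raw_x_matrix(windows, registry[name], x_at)
        peak = float(np.nanmax(np.abs(raw)))
        scales[name] = peak if peak > 0 else 1.0
    return scales


def build_feature_matrix(
    windows: pd.DataFrame,
    registry: IndicatorRegistry,
    feature_sets: Sequence[str] = FEATURE_SETS,
    a: float = 50.0,
    b: float = 0.6,
    x_at: str = "end",
    renormalize: bool = False,
    scale_max: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Assemble the samples x features table from a window table.

    Columns are grouped by provenance: per-year originals ``{IND}_y1..y4``,
    per-interval ``{IND}_DNF1..3`` and ``{IND}_DSF1..3``, and one
    ``{IND}_DFF`` per indicator, plus the metadata and ``ms_result`` label
    carried over from the windows. Returns the table and the scaling
    constants actually used (fitted on these windows when not supplied and
    not already frozen in the registry).
    """
    unknown = set(feature_sets) - set(FEATURE_SETS)
    if unknown:
        raise ConfigurationError(f"unknown feature sets {sorted(unknown)}")
    if x_at not in ("end", "mid"):
        raise ConfigurationError(f"x_at must be 'end' or 'mid', got {x_at!r}")
    indicators = [s.name for s in registry if f"{s.name}_y1" in windows.columns]

    used_scales: dict[str, float] = {}
    if "dff" in feature_sets:
        fitted = None
        for name in indicators:
            if scale_max is not None and name in scale_max:
                used_scales[name] = float(scale_max[name])
            elif registry[name].scale_max is not None:
                used_scales[name] = float(registry[name].scale_max)
            else:
                if fitted is None:
                    fitted = fit_scale_max(windows, registry, indicators, x_at)
                used_scales[name] = fitted[name]

    meta_cols = [
        c for c in ("window_id", "subject_id", "sex", "age_at_label", "age_group")
        if c in windows.columns
    ]
    columns: dict[str, np.ndarray] = {c: windows[c].to_numpy() for c in meta_cols}
    weights = _decay_weights(b, renormalize)

    for name in indicators:
        spec = registry[name]
        v = _year_block(windows, name)
        if np.isnan(v).any():
            raise MissingDataError(f"{name}: missing values in window years")
        if "original" in feature_sets:
            for k in range(N_INPUT_YEARS):
                columns[f"{name}_y{k + 1}"] = v[:, k]
        dnf = v[:, 1:] - v[:, :-1]
        if "dnf" in feature_sets:
            for k in range(3):
                columns[f"{name}_DNF{k + 1}"] = dnf[:, k]
        if "dsf" in feature_sets:
            if spec.sex_specific:
                limit = _per_row_limit(windows, spec)[:, None]
                if spec.risk_direction == "high":
                    states = (v >= limit) if spec.inclusive else (v > limit)
                else:
                    states = (v <= limit) if spec.inclusive else (v < limit)
            else:
                states = abnormal_state(v, spec)
            states = states.astype(int)
            for k in range(3):
                columns[f"{name}_DSF{k + 1}"] = states[:, k + 1] - states[:, k]
        if "dff" in feature_sets:
            raw_x = _raw_x_matrix(windows, spec, x_at)
            s = sigmoid_weight(raw_x / used_scales[name], a)
            columns[f"{name}_DFF"] = (dnf * s) @ weights

    if "ms_result" in windows.columns:
        columns["ms_result"] = windows["ms_result"].to_numpy(int)
    return pd.DataFrame(columns, index=windows.index), used_scales


def feature_groups(columns: Sequence[str]) -> dict[str, list[str]]:
    """Partition feature-matrix columns by provenance tag.

    Tags: ``meta``, ``original`` (all four years), ``original_latest``
    (year-4 originals, a subset of ``original``), ``dnf``, ``dsf``, ``dff``,
    ``label``.
    """
    groups: dict[str, list[str]] = {
        "meta": [], "original": [], "original_latest": [],
        "dnf": [], "dsf": [], "dff": [], "label": [],
    }
    for col in columns:
        if col == "ms_result":
            groups["label"].append(col)
        elif "_DNF" in col:
            groups["dnf"].append(col)
        elif "_DSF" in col:
            groups["dsf"].append(col)
        elif col.endswith("_DFF"):
            groups["dff"].append(col)
        elif len(col) > 3 and col[-3:-1] == "_y" and col[-1].isdigit():
            groups["original"].append(col)
            if col.endswith("_y4"):
                groups["original_latest"].append(col)
        else:
            groups["meta"].append(col)
    return groups
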