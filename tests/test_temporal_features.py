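"""DNF / DSF / DFF constructions and the sigmoid risk weight."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metsflow.errors import ConfigurationError, MissingDataError
from metsflow.reference_ranges import IndicatorSpec
from metsflow.temporal_features import (
    build_feature_matrix,
    compute_dff,
    compute_dnf,
    compute_dsf,
    feature_groups,
    fit_scale_max,
    flag_abnormal_dff,
    flag_abnormal_dnf,
    scale_x,
    sigmoid_weight,
)

TG_SPEC = IndicatorSpec(
    name="TG", units="mmol/L", risk_direction="high", upper=1.70,
    inclusive=True, scale_max=1.0,
)
HDL_SPEC = IndicatorSpec(
    name="HDL-C", units="mmol/L", risk_direction="low", lower=1.04,
    inclusive=True, scale_max=1.0,
)


def test_sigmoid_center_is_half_for_any_steepness():
    for a in (0.1, 1.0, 50.0, 1e4):
        assert sigmoid_weight(0.0, a) == 0.5


def test_sigmoid_limits_clamped_in_open_interval():
    lo = sigmoid_weight(-1e9, 50.0)
    hi = sigmoid_weight(1e9, 50.0)
    assert 0.0 < lo < 1e-10 and 1.0 - 1e-10 < hi < 1.0


def test_sigmoid_closed_form_value():
    # a * x = -1  =>  1 / (1 + e)
    assert sigmoid_weight(-0.02, 50.0) == pytest.approx(1.0 / (1.0 + math.e), abs=1e-12)


def test_sigmoid_strictly_increasing():
    xs = np.linspace(-0.5, 0.5, 101)
    ws = sigmoid_weight(xs, 50.0)
    assert (np.diff(ws) > 0).all()


def test_sigmoid_rejects_nonpositive_steepness():
    with pytest.raises(ConfigurationError):
        sigmoid_weight(0.0, 0.0)


def test_dnf_is_current_minus_past():
    assert compute_dnf(1.2, 1.8) == pytest.approx(0.6)
    assert compute_dnf(3.3, 3.3) == 0.0
    assert compute_dnf(2.0, 1.5) == pytest.approx(-0.5)


def test_scale_x_sign_and_scaling():
    assert scale_x(1.70, TG_SPEC) == 0.0
    assert sigmoid_weight(scale_x(1.70, TG_SPEC)) == 0.5
    # deficit-type: worse (lower) HDL-C gives positive risk distance
    assert scale_x(0.90, HDL_SPEC) == pytest.approx(0.14)
    spec = IndicatorSpec(name="X", units="u", upper=0.0, scale_max=10.0)
    assert scale_x(5.0, spec) == pytest.approx(0.5)


def test_scale_x_requires_scale_max():
    spec = IndicatorSpec(name="X", units="u", upper=1.0)
    with pytest.raises(ConfigurationError, match="scale_max"):
        scale_x(2.0, spec)


def test_risk_direction_symmetry():
    """Reflecting values about the limit with flipped direction keeps |x|."""
    high = IndicatorSpec(name="H", units="u", upper=10.0, scale_max=2.0)
    low = IndicatorSpec(
        name="L", units="u", lower=10.0, risk_direction="low", scale_max=2.0
    )
    for v in (7.0, 10.0, 12.5):
        assert scale_x(v, high) == pytest.approx(-scale_x(v, low))


def test_dff_constant_series_is_zero():
    assert compute_dff([1.3, 1.3, 1.3, 1.3], TG_SPEC).g == 0.0


def test_dff_recent_jump_outweighs_old_jump():
    recent = compute_dff([1.0, 1.0, 1.0, 1.6], TG_SPEC)
    old = compute_dff([1.0, 1.6, 1.6, 1.6], TG_SPEC)
    assert abs(recent.g) > abs(old.g)  # weight b > b^3


def test_dff_hand_computed_oracle():
    """Spreadsheet-style recomputation of the three-term sum."""
    values, limit, a, b = [1.0, 1.2, 1.5, 1.9], 1.70, 50.0, 0.6
    raw_x = [v - limit for v in values[1:]]
    scale = max(abs(x) for x in raw_x)
    spec = IndicatorSpec(name="TG", units="mmol/L", upper=limit, scale_max=scale)
    expected = 0.0
    for k, w in enumerate((b**3, b**2, b)):
        dnf = values[k + 1] - values[k]
        s = 1.0 / (1.0 + math.exp(-a * raw_x[k] / scale))
        expected += w * dnf * s
    got = compute_dff(values, spec, a=a, b=b)
    assert got.g == pytest.approx(expected, abs=1e-12)
    assert [t.dnf for t in got.terms] == pytest.approx([0.2, 0.3, 0.4])


def test_dff_naive_loop_equivalence_on_random_series():
    rng = np.random.default_rng(8)
    spec = IndicatorSpec(name="TG", units="mmol/L", upper=1.70, scale_max=2.0)
    for _ in range(1000):
        values = rng.uniform(0.3, 4.0, size=4)
        naive = 0.0
        for k, w in enumerate((0.6**3, 0.6**2, 0.6)):
            dnf = values[k + 1] - values[k]
            s = 1.0 / (1.0 + math.exp(-50.0 * (values[k + 1] - 1.70) / 2.0))
            naive += w * dnf * s
        assert compute_dff(values, spec).g == pytest.approx(naive, abs=1e-12)


def test_dff_midpoint_evaluation_flag():
    values = [1.0, 1.2, 1.5, 1.9]
    end = compute_dff(values, TG_SPEC, x_at="end")
    mid = compute_dff(values, TG_SPEC, x_at="mid")
    assert [t.x for t in mid.terms] == pytest.approx(
        [(a + c) / 2 - 1.70 for a, c in zip(values[:-1], values[1:])]
    )
    assert end.g != mid.g


def test_dff_renormalized_weights():
    values = [1.0, 1.2, 1.5, 1.9]
    b = 0.6
    plain = compute_dff(values, TG_SPEC, b=b)
    renorm = compute_dff(values, TG_SPEC, b=b, renormalize=True)
    assert renorm.g == pytest.approx(plain.g / (b**3 + b**2 + b), abs=1e-12)


def test_dff_missing_year_raises():
    with pytest.raises(MissingDataError):
        compute_dff([1.0, float("nan"), 1.2, 1.3], TG_SPEC)


@given(
    base=st.floats(0.5, 3.0),
    dnf=st.floats(0.05, 1.0),
    shift=st.floats(0.01, 1.0),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_dff_monotone_in_risk_distance_when_rising(base, dnf, shift):
    """With positive deltas fixed, ending further on the risk side raises g.

    Uses a gentle steepness so the sigmoid stays away from its clamped
    saturation plateaus across the sampled range.
    """
    a = 5.0
    lower = compute_dff([base - 2 * dnf, base - dnf, base, base + dnf],
                        TG_SPEC, a=a).g
    higher_base = base + shift
    higher = compute_dff(
        [higher_base - 2 * dnf, higher_base - dnf, higher_base, higher_base + dnf],
        TG_SPEC, a=a,
    ).g
    assert higher > lower


@pytest.mark.parametrize(
    "prev,curr,expected",
    [(1.0, 2.0, 1), (2.0, 2.5, 0), (2.0, 1.0, -1), (1.0, 1.2, 0)],
)
def test_dsf_state_difference(prev, curr, expected):
    assert compute_dsf(prev, curr, TG_SPEC) == expected


def test_dsf_for_deficit_indicator():
    assert compute_dsf(1.5, 0.9, HDL_SPEC) == 1   # normal -> abnormal
    assert compute_dsf(0.9, 1.5, HDL_SPEC) == -1


def test_abnormal_dnf_strictly_positive():
    assert flag_abnormal_dnf(0.3)
    assert not flag_abnormal_dnf(0.0)
    assert not flag_abnormal_dnf(-0.3)


def test_abnormal_dff_vs_mean_of_absolutes():
    flags = flag_abnormal_dff([1.0, -1.0, 4.0])  # mean |g| = 2
    assert flags.tolist() == [False, False, True]
    assert not flag_abnormal_dff([2.0, 2.0, -2.0]).any()  # strict inequality
    flags = flag_abnormal_dff([0.0, 0.0, 0.1])
    assert flags.tolist() == [False, False, True]
    with pytest.raises(ConfigurationError):
        flag_abnormal_dff([])


def test_decay_weight_ordering():
    b = 0.6
    assert b**3 < b**2 < b


def test_feature_matrix_layout_and_scalar_agreement(windows, registry):
    feats, scales = build_feature_matrix(windows, registry)
    groups = feature_groups(feats.columns)
    n_ind = 18
    assert len(groups["original"]) == 4 * n_ind
    assert len(groups["original_latest"]) == n_ind
    assert len(groups["dnf"]) == 3 * n_ind
    assert len(groups["dsf"]) == 3 * n_ind
    assert len(groups["dff"]) == n_ind
    assert groups["label"] == ["ms_result"]
    assert not feats[groups["dff"]].isna().any().any()
    # vectorized DFF equals the scalar construction row by row
    import dataclasses

    spec = dataclasses.replace(registry["TG"], scale_max=scales["TG"])
    for i in range(0, len(feats), max(1, len(feats) // 25)):
        row = windows.iloc[i]
        values = [row[f"TG_y{k}"] for k in range(1, 5)]
        assert feats["TG_DFF"].iloc[i] == pytest.approx(
            compute_dff(values, spec, sex=row["sex"]).g, abs=1e-12
        )
    # DNF columns are plain year differences
    np.testing.assert_allclose(
        feats["TG_DNF3"], windows["TG_y4"] - windows["TG_y3"], atol=1e-12
    )


def test_fit_scale_max_is_peak_absolute_distance(windows, registry):
    scales = fit_scale_max(windows, registry, indicators=["TG"])
    v = windows[[f"TG_y{k}" for k in (2, 3, 4)]].to_numpy()
    assert scales["TG"] == pytest.approx(np.abs(v - 1.70).max())


def test_feature_matrix_selected_sets(windows, registry):
    feats, _ = build_feature_matrix(windows, registry, feature_sets=("original",))
    groups = feature_groups(feats.columns)
    assert groups["dnf"] == [] and groups["dff"] == []
    with pytest.raises(ConfigurationError):
        build_feature_matrix(windows, registry, feature_sets=("bogus",))
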