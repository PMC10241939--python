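"""Generator contracts: marginal recovery, temporal structure, planted signal."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metsflow.errors import ConfigurationError
from metsflow.reference_ranges import diagnose_frame
from metsflow.synthetic_cohort import (
    FLOORS,
    INDICATORS,
    TABLE_MARGINALS,
    CohortConfig,
    _fit_truncnorm,
    generate_cohort,
    inject_missingness,
    to_long,
    to_wide,
    window_incidence,
    write_cohort,
)


@pytest.fixture(scope="module")
def big_cohort():
    # fixed magnitude: marginal/autocorrelation checks do not need calibration
    return generate_cohort(CohortConfig(n_subjects=5000, seed=29, drift_magnitude=0.45))


def test_year1_marginals_within_3_se(big_cohort):
    y1 = big_cohort[big_cohort["year"] == 1]
    for sex in ("male", "female"):
        sub = y1[y1["sex"] == sex]
        for name in INDICATORS + ("age",):
            mean, sd = TABLE_MARGINALS[sex][name]
            col = sub["age"] if name == "age" else sub[name]
            se = sd / np.sqrt(len(sub))
            assert abs(col.mean() - mean) < 3 * se, (sex, name)


def test_year1_ks_against_configured_marginal(big_cohort):
    y1 = big_cohort[(big_cohort["year"] == 1) & (big_cohort["sex"] == "male")]
    for name in ("TG", "WC", "HDL-C"):
        mean, sd = TABLE_MARGINALS["male"][name]
        dist = _fit_truncnorm(mean, sd, FLOORS[name])
        d, _ = stats.kstest(y1[name].to_numpy(), dist.cdf)
        assert d < 0.03, name


def test_lag1_autocorrelation_recovered(big_cohort):
    cfg_rho = 0.85
    nondrift = big_cohort[~big_cohort["drift_group"]]
    for name in ("PLT", "HGB", "TC"):  # indicators without planted drift
        # within sex: pooling sexes would inflate r via the mean difference
        for sex in ("male", "female"):
            sub = nondrift[nondrift["sex"] == sex]
            wide = sub.pivot_table(index="subject_id", columns="year", values=name)
            prev = np.concatenate([wide[t].to_numpy() for t in range(1, 5)])
            curr = np.concatenate([wide[t + 1].to_numpy() for t in range(1, 5)])
            r = np.corrcoef(prev, curr)[0, 1]
            assert abs(r - cfg_rho) < 0.05, (name, sex, r)


def test_no_drift_no_structure_deltas_centered():
    cfg = CohortConfig(
        n_subjects=800, seed=2, drift_fraction=0.0, drift_magnitude=0.0,
        subject_effect=0.0, transient_noise=0.3, autocorrelation=0.0,
    )
    cohort = generate_cohort(cfg)
    for name in ("TG", "SBP", "WC"):
        wide = cohort.pivot_table(index="subject_id", columns="year", values=name)
        deltas = np.concatenate(
            [(wide[t + 1] - wide[t]).to_numpy() for t in range(1, 5)]
        )
        _, sd = TABLE_MARGINALS["male"][name]
        assert abs(deltas.mean()) < 4 * deltas.std() / np.sqrt(len(deltas)), name


def test_fixed_seed_byte_identical_csv(tmp_path):
    cfg = CohortConfig(n_subjects=150, seed=13, drift_magnitude=0.4)
    buf1, buf2 = io.StringIO(), io.StringIO()
    write_cohort(generate_cohort(cfg), buf1)
    write_cohort(generate_cohort(cfg), buf2)
    assert buf1.getvalue() == buf2.getvalue()


def test_calibrated_incidence_within_band():
    cfg = CohortConfig(n_subjects=3000, seed=17)  # drift_magnitude calibrated
    inc = window_incidence(generate_cohort(cfg))
    assert abs(inc - cfg.target_incidence) / cfg.target_incidence < 0.30


def test_drift_group_has_more_conditions_in_label_year(big_cohort):
    y5 = big_cohort[big_cohort["year"] == 5]
    n_met = diagnose_frame(y5)["n_conditions_met"]
    drift = y5["drift_group"].to_numpy()
    assert n_met[drift].mean() > n_met[~drift].mean()


def test_drifting_indicators_trend_toward_thresholds(big_cohort):
    drifters = big_cohort[big_cohort["drift_group"]]
    wide = drifters.pivot_table(index="subject_id", columns="year", values="TG")
    assert (wide[5] - wide[1]).mean() > 0.2  # clearly positive mean trend
    wide = drifters.pivot_table(index="subject_id", columns="year", values="HDL-C")
    assert (wide[5] - wide[1]).mean() < 0.0  # deficit marker worsens downward


def test_raw_anthropometrics_are_coherent(big_cohort):
    np.testing.assert_allclose(
        big_cohort["WHR"], big_cohort["WC"] / big_cohort["hip"], rtol=1e-9
    )
    np.testing.assert_allclose(
        big_cohort["BMI"],
        big_cohort["weight"] / (big_cohort["height"] / 100.0) ** 2,
        rtol=1e-9,
    )


def test_inject_missingness_rates():
    cohort = generate_cohort(CohortConfig(n_subjects=2000, seed=3, drift_magnitude=0.0))
    out = inject_missingness(cohort, {"CR": 0.10}, seed=4)
    n_missing = int(out["CR"].isna().sum())
    # binomial 99% interval around 0.10 * 10,000
    assert 900 <= n_missing <= 1100
    same = inject_missingness(cohort, {"CR": 0.0}, seed=4)
    pd.testing.assert_frame_equal(same, cohort)
    with pytest.raises(ConfigurationError):
        inject_missingness(cohort, {"CR": 1.5}, seed=0)


def test_long_wide_roundtrip():
    cohort = generate_cohort(
        CohortConfig(n_subjects=40, seed=5, drift_magnitude=0.0,
                     include_raw_anthro=False)
    )
    back = to_wide(to_long(cohort))
    merged = back.merge(
        cohort[["subject_id", "year"] + list(INDICATORS)],
        on=["subject_id", "year"], suffixes=("", "_orig"),
    )
    for name in INDICATORS:
        np.testing.assert_allclose(merged[name], merged[f"{name}_orig"])


def test_config_validation():
    with pytest.raises(ConfigurationError):
        CohortConfig(n_subjects=0)
    with pytest.raises(ConfigurationError):
        CohortConfig(n_subjects=10, drift_fraction=1.0)
    with pytest.raises(ConfigurationError):
        CohortConfig(n_subjects=10, target_incidence=0.0)
    with pytest.raises(ConfigurationError):
        CohortConfig(n_subjects=10, subject_effect=0.6, transient_noise=0.5)
    with pytest.raises(ConfigurationError):
        # total lag-1 correlation below the stable share is infeasible
        CohortConfig(n_subjects=10, autocorrelation=0.2, subject_effect=0.6)


def test_lognormal_option_matches_moments():
    cfg = CohortConfig(
        n_subjects=4000, seed=23, drift_magnitude=0.0, drift_fraction=0.0,
        log_scale=frozenset({"TG"}), include_raw_anthro=False,
    )
    y1 = generate_cohort(cfg).query("year == 1 and sex == 'male'")
    mean, sd = TABLE_MARGINALS["male"]["TG"]
    assert abs(y1["TG"].mean() - mean) < 3 * sd / np.sqrt(len(y1))
    assert stats.skew(y1["TG"]) > 1.0  # right-skewed as intended
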