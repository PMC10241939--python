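import pytest

from metsflow import default_registry
from metsflow.cohort_windows import build_windows
from metsflow.reference_ranges import MetSCriteria
from metsflow.risk_stats import add_abnormal_flags
from metsflow.synthetic_cohort import CohortConfig, generate_cohort
from metsflow.temporal_features import build_feature_matrix


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def criteria():
    return MetSCriteria()


@pytest.fixture(scope="session")
def cohort():
    """Mid-sized planted-signal cohort; fixed drift magnitude (no calibration)."""
    return generate_cohort(
        CohortConfig(n_subjects=1500, seed=11, drift_magnitude=0.45)
    )


@pytest.fixture(scope="session")
def windows(cohort):
    table, counts = build_windows(cohort)
    return table


@pytest.fixture(scope="session")
def features(windows, registry):
    table, _ = build_feature_matrix(windows, registry)
    return table


@pytest.fixture(scope="session")
def flagged_features(features, registry):
    return add_abnormal_flags(features, registry)
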