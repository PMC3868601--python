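import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from volranks import GroupedCohort, QuadraticTrend

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_cohort(group_values, label="custom"):
    """GroupedCohort straight from {code: values} (bypasses raw volumes)."""
    return GroupedCohort(
        label=label,
        groups={c: np.asarray(v, dtype=float) for c, v in group_values.items()},
    )


@pytest.fixture
def quadratic_cohort():
    """Noise-free cohort whose values lie exactly on one quadratic."""
    c, b1, b2 = 0.75, 0.001, -0.002
    return make_cohort(
        {code: [c + b1 * code + b2 * code**2] * 4 for code in range(1, 6)},
        label="noiseless",
    )


@pytest.fixture
def random_cohort(rng):
    """Small heteroscedastic Gaussian cohort over all five bands."""
    groups = {
        code: rng.normal(0.75 - 0.004 * code, 0.01 + 0.002 * code, size=30)
        for code in range(1, 6)
    }
    return make_cohort(groups, label="random")
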