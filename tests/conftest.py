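import pytest
from hypothesis import HealthCheck, settings

from mamsnet import DesignSpec, calibrate_design

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def trial_a_design():
    """The drug trial design: 5 arms + pooled control, 4 stages, calibrated
    at acceptance-grade Monte Carlo resolution."""
    return calibrate_design(DesignSpec(), mc_reps=100_000, seed=1805)


@pytest.fixture(scope="session")
def small_design():
    """A cheap 2-arm, 2-stage design for unit tests of the trial engine."""
    spec = DesignSpec(n_arms=2, n_stages=2, interim_fractions=(0.5, 1.0))
    return calibrate_design(spec, mc_reps=20_000, seed=7)
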