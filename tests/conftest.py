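import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grn():
    from grnode.synthetic import generate_true_grn

    return generate_true_grn(G=50, D=4, seed=11)


@pytest.fixture(scope="session")
def noiseless_cohort(small_grn):
    """Cohort with exact latent dynamics and rounded counts (no sampling noise)."""
    from grnode.synthetic import simulate_timecourse

    return simulate_timecourse(small_grn, stages=7, per_stage=11,
                               jitter_sd=0.05, noise_model="none", seed=12)


@pytest.fixture(scope="session")
def poisson_cohort(small_grn):
    from grnode.synthetic import simulate_timecourse

    return simulate_timecourse(small_grn, stages=7, per_stage=11,
                               jitter_sd=0.05, noise_model="poisson", seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
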