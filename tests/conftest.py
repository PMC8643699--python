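import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def trial():
    """One default synthetic trial (23 families x 15 progeny), fixed seed."""
    from hempkite.simulate import simulate_trial

    return simulate_trial(seed=11)


@pytest.fixture(scope="session")
def trial_df(trial):
    return trial[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
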