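import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import adaptdecode as ad

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Tiny but complete penetration: 4 sites, 8 trials per sequence type."""
    return ad.SimulationConfig(n_sites=4, n_trials_per_sequence=8, seed=11)


@pytest.fixture(scope="session")
def small_session(small_config):
    return ad.generate_session(small_config)


@pytest.fixture(scope="session")
def small_band_power(small_session, small_config):
    lfp = ad.notch_filter(small_session.lfp, small_config.sampling_rate)
    return ad.compute_band_power(
        lfp,
        small_config.sampling_rate,
        small_session.trials["trial_id"].to_numpy(),
        epoch_onsets_ms={
            "adapter": small_config.adapter_onset_ms,
            "test": small_config.test_onset_ms,
        },
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
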