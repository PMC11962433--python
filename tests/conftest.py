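import pytest

from plastifate import (SyntheticExperimentConfig, build_degradation_curves,
                        simulate_incubation)


@pytest.fixture(scope="session")
def noise_free_config():
    """Reference incubation with all stochastic knobs off."""
    return SyntheticExperimentConfig(obs_noise_sd=0.0, replicate_cv=0.0,
                                     blank_rate=0.0, seed=42)


@pytest.fixture(scope="session")
def noise_free_series(noise_free_config):
    return simulate_incubation(noise_free_config)


@pytest.fixture(scope="session")
def noise_free_curves(noise_free_series):
    return build_degradation_curves(noise_free_series)


@pytest.fixture(scope="session")
def noisy_config():
    """Reference incubation at realistic noise/variability settings."""
    return SyntheticExperimentConfig(seed=7)
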