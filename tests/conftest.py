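import numpy as np
import pytest

from priorcfc import synthetic_data as sd
from priorcfc.observers import ObserverParams


@pytest.fixture(scope="session")
def base_params() -> ObserverParams:
    """Study-scale observer: prior-component SD 30 deg, sensory SD 15 deg."""
    return ObserverParams(sigma_p=30.0, sigma_l=15.0, w=1.54, alpha=0.34)


@pytest.fixture(scope="session")
def ideal_settings(base_params):
    """Quantile-exact stimulus levels for the Bayesian-family observer."""
    return sd.ideal_stimulus_levels("bayes", base_params)


@pytest.fixture(scope="session")
def full_design(ideal_settings):
    """A complete 28-pair x 24-repetition (672 trial) design."""
    return sd.build_trial_design(ideal_settings, 24, np.random.default_rng(101))


@pytest.fixture(scope="session")
def small_design(ideal_settings):
    """Reduced 8-repetition (224 trial) design for fitting tests."""
    return sd.build_trial_design(ideal_settings, 8, np.random.default_rng(102))
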