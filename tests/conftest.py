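import numpy as np
import pytest

from neurofuse import generate_trialset, strong_effect_config


@pytest.fixture(scope="session")
def small_trialset():
    """Fast default-effect trial set (6 trials/class) for shape/contract tests."""
    ts, gt = generate_trialset(n_trials_per_class=6, seed=13)
    return ts, gt


@pytest.fixture(scope="session")
def default_trialset():
    """Full-size trial set at the default (moderate) planted contrast."""
    ts, gt = generate_trialset(n_trials_per_class=30, seed=7)
    return ts, gt


@pytest.fixture(scope="session")
def strong_trialset():
    """Full-size trial set at the strong planted contrast."""
    cfg = strong_effect_config()
    ts, gt = generate_trialset(n_trials_per_class=30, seed=7, **cfg)
    return ts, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
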