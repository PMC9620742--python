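"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from motorpop.synthgen import SynthConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """20 neurons, 10+10 trials, default class mix; cached per test run."""
    cfg = SynthConfig(n_neurons=20, n_push_trials=10, n_pull_trials=10, seed=11)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def noiseless_session():
    """Noise-free, jitter-free session for exact-recovery checks."""
    # short decay keeps each transient inside its own trial, so push and
    # pull averages can be compared exactly (no carryover between trials)
    cfg = SynthConfig(
        n_neurons=6, n_push_trials=5, n_pull_trials=5,
        noise_sd=0.0, onset_jitter_sd=0.0, kernel_rise=0.2, kernel_decay=0.5,
        seed=3,
        class_proportions={"invariant_up": 1.0},
    )
    return generate_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
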