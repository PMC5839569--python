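"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from eegtau import (
    BipolarScheme,
    SynthConfig,
    generate_session,
    preprocess_session,
    tau_timecourse,
)

PAIR_C3_P3 = BipolarScheme((("C3", "P3"),))


@pytest.fixture(scope="session")
def small_config():
    """Two referential channels, one bipolar pair, 12 trials per condition."""
    return SynthConfig(
        channel_labels=("C3", "P3"),
        n_trials_per_condition=12,
        conditions=("right", "rest"),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture(scope="session")
def small_trials(small_session):
    rec, events = small_session
    return preprocess_session(rec, events, scheme=PAIR_C3_P3)


@pytest.fixture(scope="session")
def small_tau_features(small_trials):
    return tau_timecourse(small_trials, band="wide")


@pytest.fixture(scope="session")
def default_session_tau():
    """Full-size session (40 tap + 40 rest) on one bipolar pair."""
    cfg = SynthConfig(
        channel_labels=("C3", "P3"),
        n_trials_per_condition=40,
        conditions=("right", "rest"),
        seed=101,
    )
    rec, events = generate_session(cfg)
    trials = preprocess_session(rec, events, scheme=PAIR_C3_P3)
    return tau_timecourse(trials, band="wide")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
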