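"""Autocorrelation, envelope maxima, and the exponential relaxation fit."""

import numpy as np
import pytest

from eegtau import (
    acf_local_maxima,
    fit_relaxation,
    fit_window,
    grand_average_tau,
    normalized_autocorrelation,
    tau_timecourse,
    theoretical_tau,
)
from eegtau.acf import AcfSequence
from eegtau.errors import DegenerateWindowError, EmptySetError


def acf_bruteforce(s):
    """Double-loop normalized autocorrelation (test-side oracle)."""
    s = np.asarray(s, dtype=np.float64)
    d = s - s.mean()
    denom = float(np.dot(d, d))
    n = len(d)
    return np.array([
        sum(d[t] * d[t + k] for t in range(n - k)) for k in range(n)
    ]) / denom


def test_acf_matches_bruteforce(rng):
    for _ in range(20):
        n = int(rng.integers(16, 257))
        s = rng.normal(size=n) * rng.uniform(0.1, 50)
        fast = normalized_autocorrelation(s, 256.0).values
        np.testing.assert_allclose(fast, acf_bruteforce(s), atol=1e-10)


def test_acf_zero_lag_is_one(rng):
    s = rng.normal(size=512)
    acf = normalized_autocorrelation(s, 512.0)
    assert acf.values[0] == 1.0
    assert np.all(np.abs(acf.values) <= 1.0 + 1e-9)


def test_acf_cosine_period_peak():
    fs = 1024.0
    t = np.arange(int(fs)) / fs
    s = np.cos(2 * np.pi * 8.0 * t)
    acf = normalized_autocorrelation(s, fs)
    lag_period = 128  # one period of 8 Hz at 1024 Hz
    window = acf.values[64:193]
    assert np.argmax(window) + 64 == pytest.approx(lag_period, abs=2)


def test_acf_degenerate_window():
    with pytest.raises(DegenerateWindowError):
        normalized_autocorrelation(np.zeros(128), 128.0)
    with pytest.raises(DegenerateWindowError):
        normalized_autocorrelation(np.ones(4), 128.0)


from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    s=arrays(np.float64, st.integers(16, 128),
             elements=st.floats(-100, 100, allow_nan=False)),
    scale=st.floats(0.01, 1e4),
)
def test_acf_properties_hold_for_arbitrary_windows(s, scale):
    """R(0) = 1, |R| <= 1, and scale invariance for any nondegenerate
    window."""
    try:
        acf = normalized_autocorrelation(s, 128.0)
    except DegenerateWindowError:
        assert np.ptp(s) == 0 or np.std(s) < 1e-12 * np.abs(s).max()
        return
    assert acf.values[0] == 1.0
    assert np.all(np.abs(acf.values) <= 1.0 + 1e-9)
    # scale invariance needs a well-conditioned window: near-constant
    # inputs are pure rounding noise and scale nonlinearly
    if np.std(s) > 1e-3 * max(np.abs(s).max(), 1.0):
        scaled = normalized_autocorrelation(scale * s, 128.0)
        np.testing.assert_allclose(acf.values, scaled.values, atol=1e-8)


def test_acf_scale_invariance(rng):
    s = rng.normal(size=256)
    a = normalized_autocorrelation(s, 256.0).values
    b = normalized_autocorrelation(-3.7e4 * s, 256.0).values
    np.testing.assert_allclose(a, b, atol=1e-10)


# ---------------------------------------------------------------------------
# local maxima


def test_local_maxima_constructed_sequence():
    acf = AcfSequence(np.array([1.0, 0.5, 0.8, 0.3, 0.6, 0.1]), fs=1.0)
    lags, vals = acf_local_maxima(acf, max_lag=5)
    np.testing.assert_array_equal(lags, [0, 2, 4])
    np.testing.assert_array_equal(vals, [1.0, 0.8, 0.6])


def test_local_maxima_monotone_gives_anchor_only():
    acf = AcfSequence(np.linspace(1.0, 0.0, 32), fs=1.0)
    lags, vals = acf_local_maxima(acf)
    np.testing.assert_array_equal(lags, [0.0])
    np.testing.assert_array_equal(vals, [1.0])


def test_local_maxima_negative_discarded():
    acf = AcfSequence(np.array([1.0, -0.5, -0.2, -0.6, 0.0, -0.1]), fs=1.0)
    lags, vals = acf_local_maxima(acf, max_lag=5)
    np.testing.assert_array_equal(lags, [0.0])  # -0.2 and 0.0 not positive


def test_local_maxima_on_damped_cosine_envelope():
    fs, tau0 = 1024.0, 0.15
    lags = np.arange(1024)
    vals = np.exp(-lags / (tau0 * fs)) * np.cos(2 * np.pi * 10.0 * lags / fs)
    acf = AcfSequence(vals, fs)
    lag_s, y = acf_local_maxima(acf)
    assert len(lag_s) >= 4
    np.testing.assert_allclose(y, np.exp(-lag_s / tau0), rtol=0.02)


# ---------------------------------------------------------------------------
# exponential fit


def test_fit_exact_recovery():
    t = np.array([0.0, 0.05, 0.1, 0.2, 0.4])
    y = np.exp(-t / 0.2)
    fit = fit_relaxation(t, y)
    assert fit.valid
    assert fit.tau == pytest.approx(0.2, abs=1e-6)
    assert fit.r_squared > 0.9999
    assert fit.C == 1.0


def test_fit_two_points_invalid():
    fit = fit_relaxation(np.array([0.0, 0.1]), np.array([1.0, 0.5]))
    assert not fit.valid
    assert np.isnan(fit.tau)


def grid_search_tau(t, y, n=100_000):
    taus = np.geomspace(1e-4, 10.0, n)
    sse = ((np.exp(-t[None, :] / taus[:, None]) - y[None, :]) ** 2).sum(1)
    return taus[np.argmin(sse)]


def test_fit_agrees_with_grid_search_oracle(rng):
    for _ in range(10):
        tau_true = rng.uniform(0.05, 0.5)
        t = np.sort(rng.uniform(0.0, 0.6, size=8))
        t[0] = 0.0
        y = np.exp(-t / tau_true) + rng.normal(0, 0.02, size=t.size)
        y[0] = 1.0
        fit = fit_relaxation(t, y)
        assert fit.valid
        assert fit.tau == pytest.approx(grid_search_tau(t, y), abs=1e-4)


def test_fit_scale_invariance_through_acf(rng):
    s = rng.normal(size=1024)
    f1 = fit_window(s, 1024.0)
    f2 = fit_window(7.3 * s, 1024.0)
    assert f1.tau == pytest.approx(f2.tau, abs=1e-9)


# ---------------------------------------------------------------------------
# timecourse and averaging


def test_tau_monotone_in_pole_radius(rng):
    """Median fitted tau strictly increases with rho on 1 s AR windows."""
    from scipy.signal import lfilter

    fs = 1024.0
    medians = []
    for rho in (0.95, 0.97, 0.99, 0.995):
        a1 = 2 * rho * np.cos(2 * np.pi * 10 / fs)
        x = lfilter([1.0], [1.0, -a1, rho**2],
                    rng.normal(size=int(100 * fs) + 4096))[4096:]
        taus = [fit_window(x[k * 1024:(k + 1) * 1024], fs).tau
                for k in range(100)]
        medians.append(np.nanmedian(taus))
    assert all(a < b for a, b in zip(medians, medians[1:]))


@pytest.fixture(scope="module")
def movement_tau_features():
    """40 movement trials on one bipolar pair (for the timing contrast)."""
    from eegtau import (SynthConfig, generate_session, preprocess_session,
                        tau_timecourse)
    from tests.conftest import PAIR_C3_P3

    cfg = SynthConfig(channel_labels=("C3", "P3"),
                      n_trials_per_condition=40, conditions=("right",),
                      seed=43)
    rec, events = generate_session(cfg)
    trials = preprocess_session(rec, events, scheme=PAIR_C3_P3)
    return tau_timecourse(trials, band="wide")


def test_tau_timecourse_movement_exceeds_rest(movement_tau_features):
    """Intention windows carry longer relaxation times than pre-onset rest."""
    move = movement_tau_features
    intent = move[(move.end_time >= 0.0) & (move.end_time <= 1.0)]
    base = move[(move.end_time >= -2.0) & (move.end_time <= -1.0)]
    per_trial_diff = (intent.groupby("trial")["tau"].median()
                      - base.groupby("trial")["tau"].median())
    # one-sided sign test at alpha = 0.05
    from scipy.stats import binomtest

    n_pos = int((per_trial_diff > 0).sum())
    res = binomtest(n_pos, len(per_trial_diff), 0.5, alternative="greater")
    assert res.pvalue < 0.05


def test_tau_timecourse_shape_and_validity(small_tau_features, small_trials):
    df = small_tau_features
    assert len(df) == small_trials.n_trials * 51
    assert set(df.columns) >= {"trial", "channel", "condition", "end_time",
                               "tau", "r_squared", "valid"}
    assert df["valid"].mean() > 0.95
    ok = df[df["valid"]]
    assert ((ok["r_squared"] >= 0.0) & (ok["r_squared"] <= 1.0)).mean() > 0.9
    assert (ok["tau"] > 0).all()


def test_constant_trial_flagged_invalid(small_trials):
    from eegtau.prep import TrialSet

    epochs = np.zeros((1, 1, small_trials.epochs.shape[-1]))
    flat = TrialSet(epochs, small_trials.time_axis, ["rest"],
                    small_trials.fs, ["C3-P3"])
    df = tau_timecourse(flat, band="wide")
    assert not df["valid"].any()


def test_grand_average_tau_degenerate_and_missing(small_tau_features):
    import pandas as pd

    first_right = small_tau_features.loc[
        small_tau_features.condition == "right", "trial"].iloc[0]
    one = small_tau_features[(small_tau_features.trial == first_right)
                             & (small_tau_features.condition == "right")]
    stacked = pd.concat(
        [one.assign(trial=i) for i in range(10)], ignore_index=True
    )
    g = grand_average_tau(stacked)
    np.testing.assert_allclose(g["sd"], 0.0, atol=1e-12)
    assert (g["count"] == 10).all()
    # one all-invalid series: means computed from the rest
    bad = one.assign(trial=10, valid=False)
    g2 = grand_average_tau(pd.concat([stacked, bad], ignore_index=True))
    assert (g2["count"] == 10).all()


def test_grand_average_tau_empty():
    import pandas as pd

    empty = pd.DataFrame({"channel": [], "condition": [], "end_time": [],
                          "tau": [], "valid": []})
    with pytest.raises(EmptySetError):
        grand_average_tau(empty)
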