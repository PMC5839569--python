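"""Autocorrelation relaxation time: ACF, envelope maxima, exponential fit.

The normalized autocorrelation of a demeaned window s(0..N-1) is

    R(d) = sum_t (s(t) - sbar)(s(t+d) - sbar) / sum_t (s(t) - sbar)^2,

the biased estimator with R(0) = 1.  For a damped-oscillatory signal the
ACF is a damped cosine; its decay is summarised by fitting exp(-t / tau)
(amplitude fixed at 1 since the ACF is normalized) to the positive local
maxima of R over the first half of the positive lags.  The fitted tau — the
relaxation time — is the per-window feature used for movement-intention
classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import DegenerateWindowError, EmptySetError
from .prep import TrialSet, WindowSpec, bandpass, sliding_windows

logger = logging.getLogger(__name__)

TAU_BOUNDS = (1e-4, 10.0)
_TAU_GRID = np.geomspace(TAU_BOUNDS[0], TAU_BOUNDS[1], 400)


@dataclass
class AcfSequence:
    """Normalized autocorrelation values at lags 0..L (samples)."""

    values: np.ndarray
    fs: float

    @property
    def lags(self) -> np.ndarray:
        return np.arange(len(self.values))

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class RelaxationFit:
    """Exponential-decay fit exp(-t/tau) to ACF envelope maxima; C = 1."""

    tau: float
    r_squared: float
    n_points: int
    valid: bool
    C: float = 1.0

    @classmethod
    def invalid(cls, n_points: int = 0) -> "RelaxationFit":
        return cls(tau=np.nan, r_squared=np.nan, n_points=n_points,
                   valid=False)


def normalized_autocorrelation(values: np.ndarray, fs: float) -> AcfSequence:
    """Biased normalized ACF of one window, computed via FFT.

    Raises :class:`DegenerateWindowError` for zero-variance input.
    """
    d = np.asarray(values, dtype=np.float64)
    if d.size < 8:
        raise DegenerateWindowError(f"window too short (N={d.size})")
    d = d - d.mean()
    denom = np.dot(d, d)
    if denom <= 0.0 or not np.isfinite(denom):
        raise DegenerateWindowError("window has zero variance")
    n = d.size
    f = np.fft.rfft(d, 2 * n)
    r = np.fft.irfft(f * np.conj(f))[:n] / denom
    r[0] = 1.0
    return AcfSequence(values=r, fs=fs)


def acf_local_maxima(
    acf: AcfSequence, max_lag: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(lag seconds, value) of the anchor (0, 1) plus positive local maxima.

    The search covers lags 1..max_lag (default: half the positive lags,
    floor(N/2)).  A plateau counts once, at its first sample; only strictly
    positive maxima are kept, since the decay model is positive.
    """
    if max_lag is None:
        max_lag = acf.n // 2
    v = acf.values[: max_lag + 1]
    # strict rise from the left; fall at the first strictly lower value right
    rises = np.flatnonzero(v[1:-1] > v[:-2]) + 1
    keep = []
    for i in rises:
        j = i
        while j + 1 <= max_lag and v[j + 1] == v[i]:
            j += 1
        if j + 1 <= max_lag and v[j + 1] < v[i] and v[i] > 0.0:
            keep.append(i)
    lags = np.concatenate([[0], keep]).astype(np.int64)
    vals = np.concatenate([[1.0], v[keep] if keep else []])
    return lags / acf.fs, vals


def fit_relaxation(
    lag_seconds: np.ndarray, values: np.ndarray
) -> RelaxationFit:
    """Least-squares fit of exp(-t/tau) with C fixed at 1.

    The SSE is minimised over tau in [1e-4, 10] s by a 400-point
    log-spaced grid scan followed by bounded 1-D refinement, so the global
    minimum is found even when the SSE has local minima.  R^2 is 1 -
    SSE/SST with SST about the mean of the fitted values (anchor included).
    """
    t = np.asarray(lag_seconds, dtype=np.float64)
    y = np.asarray(values, dtype=np.float64)
    if t.size < 3:
        return RelaxationFit.invalid(n_points=t.size)

    sse_grid = ((np.exp(-t[None, :] / _TAU_GRID[:, None]) - y) ** 2).sum(axis=1)
    i = int(np.argmin(sse_grid))
    lo = _TAU_GRID[max(i - 1, 0)]
    hi = _TAU_GRID[min(i + 1, len(_TAU_GRID) - 1)]

    def sse(tau: float) -> float:
        return float(((np.exp(-t / tau) - y) ** 2).sum())

    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-9})
    if not res.success:
        logger.warning("relaxation fit did not converge: %s", res.message)
        return RelaxationFit.invalid(n_points=t.size)
    tau = float(res.x)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - res.fun / sst if sst > 0 else np.nan
    return RelaxationFit(tau=tau, r_squared=r2, n_points=int(t.size),
                         valid=True)


def fit_window(values: np.ndarray, fs: float) -> RelaxationFit:
    """ACF -> envelope maxima -> exponential fit for one window."""
    try:
        acf = normalized_autocorrelation(values, fs)
    except DegenerateWindowError:
        return RelaxationFit.invalid()
    lags_s, vals = acf_local_maxima(acf)
    return fit_relaxation(lags_s, vals)


def tau_timecourse(
    trials: TrialSet,
    band="wide",
    spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Relaxation time per trial x channel x window, long format.

    Columns: trial, channel, condition, end_time, tau, r_squared, valid.
    Trials where more than half the windows fail are flagged invalid in
    every row and excluded from classification downstream.
    """
    spec = spec or WindowSpec()
    span = trials.span
    filtered = bandpass(trials.epochs, band, trials.fs)
    rows = []
    for ti in range(trials.n_trials):
        for ci, ch in enumerate(trials.channel_labels):
            fits = [
                (w.end_time, fit_window(w.values, trials.fs))
                for w in sliding_windows(filtered[ti, ci], trials.fs, spec,
                                         span)
            ]
            n_bad = sum(not f.valid for _, f in fits)
            trial_ok = n_bad <= len(fits) / 2
            if not trial_ok:
                logger.warning(
                    "trial %d channel %s: %d/%d windows invalid; flagged",
                    ti, ch, n_bad, len(fits),
                )
            for end_time, f in fits:
                rows.append(
                    (ti, ch, trials.conditions[ti], end_time, f.tau,
                     f.r_squared, f.valid and trial_ok)
                )
    df = pd.DataFrame(
        rows,
        columns=["trial", "channel", "condition", "end_time", "tau",
                 "r_squared", "valid"],
    )
    ok = df.loc[df["valid"], "r_squared"]
    if len(ok):
        logger.info(
            "relaxation fits: %d/%d valid, R^2 median %.3f [%.3f, %.3f]",
            len(ok), len(df), ok.median(), ok.quantile(0.05),
            ok.quantile(0.95),
        )
    return df


def grand_average_tau(df: pd.DataFrame) -> pd.DataFrame:
    """Pointwise mean/sd/count of tau over trials per channel x condition.

    Invalid windows are ignored; counts report how many trials contributed
    to each point.
    """
    valid = df[df["valid"] & np.isfinite(df["tau"])]
    if valid.empty:
        raise EmptySetError("no valid relaxation fits to average")
    g = valid.groupby(["channel", "condition", "end_time"])["tau"]
    out = g.agg(mean="mean", sd="std", count="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out
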