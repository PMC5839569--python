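"""Event-related desynchronization by the band-power method, plus ERSP.

ERD expresses window band power A(i) relative to a pre-movement baseline R:

    ERD(i) = (A(i) - R) / R * 100    [percent]

Power is the squared band-passed signal smoothed by linear-interpolation
envelopes through its local extrema; the baseline is the mean over
[-2.0, -1.5] s before tap onset.  The grand-average variant removes the
evoked (phase-locked) component by subtracting the pointwise cross-trial
mean before squaring, then averages power over trials.  The ERSP view is
the movement-minus-rest difference of condition-average spectrograms in dB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import spectrogram

from .errors import BaselineError, EmptySetError
from .prep import TrialSet, WindowSpec, bandpass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ErdConfig:
    band: object = "mu"
    baseline_interval: tuple[float, float] = (-2.0, -1.5)

    def validate(self, span: tuple[float, float]) -> None:
        lo, hi = self.baseline_interval
        if not (-span[0] <= lo < hi <= 0.0):
            raise BaselineError(
                "baseline interval must precede onset and lie in the epoch"
            )


@dataclass
class ErspMap:
    times: np.ndarray
    freqs: np.ndarray
    values: np.ndarray  # dB, movement minus rest


def _envelope(sq: np.ndarray, kind: str) -> np.ndarray:
    """Linear interpolation through strict local maxima (or minima)."""
    v = sq if kind == "upper" else -sq
    idx = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])) + 1
    if idx.size < 2:
        return sq.copy()
    xs = np.concatenate([[0], idx, [sq.size - 1]])
    return np.interp(np.arange(sq.size), xs, sq[xs])


def power_envelope(x: np.ndarray, mode: str = "upper") -> np.ndarray:
    """Smoothed instantaneous power of a band-passed, zero-mean signal.

    Squares ``x`` and interpolates linearly through the strict local maxima
    (and, for ``mode="mean_of_both"``, minima) of the squared signal,
    endpoints included.  With fewer than two interior extrema the squared
    signal is returned unchanged.
    """
    x = np.asarray(x, dtype=np.float64)
    sq = x * x
    idx_max = np.flatnonzero((sq[1:-1] > sq[:-2]) & (sq[1:-1] > sq[2:])) + 1
    if idx_max.size < 2:
        logger.info("power_envelope: <2 extrema; returning squared signal")
        return sq
    upper = _envelope(sq, "upper")
    if mode == "upper":
        return upper
    if mode == "mean_of_both":
        return 0.5 * (upper + _envelope(sq, "lower"))
    raise ValueError(f"unknown envelope mode {mode!r}")


def erd_percent(a_i: float, r_base: float) -> float:
    """Eq-style percent change of window power from baseline power."""
    if r_base <= 0:
        raise BaselineError(f"baseline power must be positive; got {r_base}")
    return (a_i - r_base) / r_base * 100.0


def _window_means(power: np.ndarray, fs: float, spec: WindowSpec,
                  span: tuple[float, float]) -> np.ndarray:
    pre = span[0]
    n = spec.n_samples(fs)
    out = []
    for t in spec.end_times(span):
        start = int(round((t - spec.length + pre) * fs))
        out.append(power[start:start + n].mean())
    return np.asarray(out)


def _baseline_mean(power: np.ndarray, fs: float,
                   interval: tuple[float, float],
                   span: tuple[float, float]) -> float:
    pre = span[0]
    i0 = int(round((interval[0] + pre) * fs))
    i1 = int(round((interval[1] + pre) * fs))
    return float(power[i0:i1].mean())


def single_trial_erd(
    trials: TrialSet,
    cfg: ErdConfig | None = None,
    spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Per-trial ERD: bandpass -> square -> upper envelope -> Eq percent.

    The baseline is the upper-envelope mean over the baseline interval of
    the same trial.  Long format mirroring the tau table, with
    ``erd_percent`` in place of ``tau``.
    """
    cfg = cfg or ErdConfig()
    spec = spec or WindowSpec()
    span = trials.span
    cfg.validate(span)
    filtered = bandpass(trials.epochs, cfg.band, trials.fs)
    rows = []
    for ti in range(trials.n_trials):
        for ci, ch in enumerate(trials.channel_labels):
            power = power_envelope(filtered[ti, ci], mode="upper")
            r_base = _baseline_mean(power, trials.fs, cfg.baseline_interval,
                                    span)
            a = _window_means(power, trials.fs, spec, span)
            valid = r_base > 0
            if not valid:
                logger.warning("trial %d channel %s: non-positive baseline",
                               ti, ch)
            for t, a_i in zip(spec.end_times(span), a):
                erd = erd_percent(a_i, r_base) if valid else np.nan
                rows.append((ti, ch, trials.conditions[ti], float(t), erd,
                             valid))
    return pd.DataFrame(
        rows,
        columns=["trial", "channel", "condition", "end_time", "erd_percent",
                 "valid"],
    )


def grand_average_erd(
    trials: TrialSet,
    cfg: ErdConfig | None = None,
    spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Grand-average ERD per condition x channel.

    Per condition and channel: band-pass, subtract the pointwise cross-trial
    mean (evoked-activity removal), square, average over trials, smooth with
    the mean of upper and lower envelopes, then express each window mean
    relative to the baseline interval.  Requires >= 2 trials per condition.
    """
    cfg = cfg or ErdConfig()
    spec = spec or WindowSpec()
    span = trials.span
    cfg.validate(span)
    filtered = bandpass(trials.epochs, cfg.band, trials.fs)
    rows = []
    for cond in dict.fromkeys(trials.conditions):
        idx = [i for i, c in enumerate(trials.conditions) if c == cond]
        if len(idx) < 2:
            raise EmptySetError(
                f"grand average needs >= 2 trials; condition {cond!r} has "
                f"{len(idx)}"
            )
        sub = filtered[idx]
        residual = sub - sub.mean(axis=0, keepdims=True)
        avg_power = (residual ** 2).mean(axis=0)  # channel x sample
        for ci, ch in enumerate(trials.channel_labels):
            smooth = power_envelope(avg_power[ci], mode="mean_of_both")
            r_base = _baseline_mean(smooth, trials.fs, cfg.baseline_interval,
                                    span)
            if r_base <= 0:
                raise BaselineError(
                    f"degenerate baseline for condition {cond!r}, channel "
                    f"{ch}: all trials identical?"
                )
            a = _window_means(smooth, trials.fs, spec, span)
            for t, a_i in zip(spec.end_times(span), a):
                rows.append((cond, ch, float(t), erd_percent(a_i, r_base)))
    return pd.DataFrame(rows, columns=["condition", "channel", "end_time",
                                       "erd_percent"])


def ersp(
    trials: TrialSet,
    move_conditions=("right",),
    rest_condition: str = "rest",
    channel: str | None = None,
    seg_seconds: float = 0.5,
    overlap: float = 0.9,
    freq_range: tuple[float, float] = (0.5, 60.0),
) -> ErspMap:
    """Movement-minus-rest average spectrogram difference in dB.

    Hann segments of ``seg_seconds`` with 90% overlap, power scaling;
    spectrograms are averaged within condition before the dB difference.
    """
    if isinstance(move_conditions, str):
        move_conditions = (move_conditions,)
    move = trials.select(list(move_conditions))
    rest = trials.select(rest_condition)
    if move.n_trials < 2 or rest.n_trials < 2:
        raise EmptySetError("ersp needs >= 2 trials per condition")
    ci = (trials.channel_labels.index(channel) if channel
          else 0)
    nper = int(round(seg_seconds * trials.fs))
    nover = int(round(overlap * nper))

    def avg_spec(ts: TrialSet):
        specs = []
        for ep in ts.epochs[:, ci, :]:
            f, t, s = spectrogram(ep, fs=ts.fs, window="hann",
                                  nperseg=nper, noverlap=nover,
                                  scaling="density", mode="psd")
            specs.append(s)
        return f, t, np.mean(specs, axis=0)

    f, t, pm = avg_spec(move)
    _, _, pr = avg_spec(rest)
    keep = (f >= freq_range[0]) & (f <= freq_range[1])
    eps = np.finfo(float).tiny
    values = 10.0 * (np.log10(pm[keep] + eps) - np.log10(pr[keep] + eps))
    return ErspMap(times=t - trials.span[0], freqs=f[keep], values=values)


def write_ersp(m: ErspMap, path) -> None:
    """Delimited matrix with a time header row and frequency first column."""
    df = pd.DataFrame(m.values, index=m.freqs, columns=np.round(m.times, 4))
    df.index.name = "freq_hz"
    df.to_csv(path, sep="\t", float_format="%.6f")
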