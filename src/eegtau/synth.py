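"""Synthetic EEG sessions with known relaxation time and ERD ground truth.

Each channel is the sum of two processes resonant at ``f_osc`` plus white
measurement noise:

* a background AR(2) process with poles at ``rho * exp(+-i 2 pi f_osc /
  fs)``, whose autocorrelation is a damped cosine with envelope
  ``rho ** lag`` and e-folding time ``-1 / (fs * ln rho)`` seconds
  (:func:`theoretical_tau`).  In movement trials the pole radius switches
  from ``rho_rest`` to ``rho_move`` inside the intention interval,
  lengthening the relaxation time; innovations are rescaled so the
  stationary variance is identical for both radii, so the switch changes
  the temporal dependence, not the power.
* a mu rhythm (``mu_kind``: a second AR(2) with fixed pole radius, or a
  deterministic random-phase sinusoid for noise-free fixtures) whose
  waveform is multiplied by an ERD gain that ramps from 1 down to
  ``erd_scale`` over the half second before the tap, holds through
  [0, +1] s, and recovers by +1.5 s — attenuating mu band power by
  ``erd_scale ** 2`` in movement trials.

Rest trials are stationary.  An optional shared source (``mixing``) adds a
common signal to every channel so the bipolar montage has something to
cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter, lfilter_zi

from .errors import ConfigurationError, StabilityError

MOTOR_CHANNELS = ("F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4")
MOVEMENT_LABELS = ("right", "left")
CONDITIONS = ("right", "left", "rest")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a simulated tapping session.

    Defaults mirror a single-participant session: 1024 Hz, the nine motor
    channels, 40 trials per condition, 6 s epochs with the tap at 0 s.
    """

    fs: float = 1024.0
    channel_labels: tuple[str, ...] = MOTOR_CHANNELS
    n_trials_per_condition: int = 40
    epoch_span: tuple[float, float] = (3.0, 3.0)
    rho_rest: float = 0.99
    rho_move: float = 0.995
    f_osc: float = 10.0
    intention_interval: tuple[float, float] = (-0.5, 1.0)
    erd_scale: float = 0.5
    erd_ramp_start: float = -0.5
    erd_hold: tuple[float, float] = (0.0, 1.0)
    erd_recover: float = 1.5
    noise_sd: float = 0.1
    amplitude_uv: float = 10.0
    ar_scale: float = 1.0
    mu_scale: float = 1.0
    mu_kind: str = "ar"  # "ar" | "sinusoid"
    rho_mu: float | None = None  # default: rho_rest
    mixing: float = 0.0
    gap_range: tuple[float, float] = (1.0, 1.5)
    conditions: tuple[str, ...] = CONDITIONS
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.rho_rest < 1.0) or not (0.0 < self.rho_move < 1.0):
            raise StabilityError(
                f"pole radii must lie in (0, 1); got rest={self.rho_rest}, "
                f"move={self.rho_move}"
            )
        if self.rho_move < self.rho_rest:
            raise ConfigurationError("rho_move must be >= rho_rest")
        if self.fs <= 2.0 * self.f_osc:
            raise ConfigurationError("fs must exceed 2 * f_osc")
        pre, post = self.epoch_span
        lo, hi = self.intention_interval
        if not (-pre <= lo < hi <= post):
            raise ConfigurationError(
                "intention_interval must lie inside the epoch span"
            )
        if self.n_trials_per_condition < 1:
            raise ConfigurationError("need at least one trial per condition")
        if self.gap_range[0] < 1.0:
            raise ConfigurationError("inter-trial gap must be at least 1 s")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ConfigurationError(f"unknown conditions: {sorted(unknown)}")
        if self.mu_kind not in ("ar", "sinusoid"):
            raise ConfigurationError(f"unknown mu_kind {self.mu_kind!r}")
        if self.rho_mu is not None and not (0.0 < self.rho_mu < 1.0):
            raise StabilityError(f"rho_mu must lie in (0, 1); got {self.rho_mu}")


@dataclass
class EventList:
    """Tap onsets (sample indices) with per-event condition labels."""

    onsets: np.ndarray
    labels: list[str]
    fs: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        if len(self.onsets) != len(self.labels):
            raise ValueError("onsets and labels must have equal length")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        bad = set(self.labels) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown event labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.onsets)


def theoretical_tau(rho: float, fs: float) -> float:
    """e-folding time (s) of the AR autocorrelation envelope ``rho ** lag``.

    The envelope obeys ``rho ** (fs * t) = exp(-t / tau)`` with
    ``tau = -1 / (fs * ln rho)``.
    """
    if not (0.0 < rho < 1.0):
        raise ValueError(f"rho must lie in (0, 1); got {rho}")
    if fs <= 0:
        raise ValueError("fs must be positive")
    return -1.0 / (fs * math.log(rho))


def ar2_coefficients(rho: float, f_osc: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients for poles at ``rho * exp(+-i 2 pi f_osc / fs)``."""
    theta = 2.0 * math.pi * f_osc / fs
    return 2.0 * rho * math.cos(theta), -rho * rho


def ar2_stationary_variance(rho: float, f_osc: float, fs: float) -> float:
    """Stationary variance of the unit-innovation AR(2) process."""
    a1, a2 = ar2_coefficients(rho, f_osc, fs)
    return (1.0 - a2) / ((1.0 + a2) * ((1.0 - a2) ** 2 - a1 * a1))


def ar2_process(rho: float, f_osc: float, fs: float, n_samples: int,
                rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance resonant AR(2) sample path (with burn-in).

    The closed-form relaxation time of its autocorrelation envelope is
    :func:`theoretical_tau`; used as a ground-truth fixture for the
    relaxation-time estimator.
    """
    if not (0.0 < rho < 1.0):
        raise StabilityError(f"rho must lie in (0, 1); got {rho}")
    burn = int(20 * max(1.0, theoretical_tau(rho, fs) * fs))
    x = _piecewise_ar2(rng.standard_normal(n_samples + burn),
                       [(0, n_samples + burn, rho)], f_osc, fs)
    return x[burn:]


def _piecewise_ar2(
    innovations: np.ndarray,
    rho_segments: list[tuple[int, int, float]],
    f_osc: float,
    fs: float,
) -> np.ndarray:
    """Run an AR(2) recursion whose pole radius changes between segments.

    Filter state is carried across segment boundaries so the signal itself is
    continuous; innovations are rescaled per segment so each pole radius has
    unit stationary variance.
    """
    out = np.empty_like(innovations)
    zi = None
    for start, stop, rho in rho_segments:
        a1, a2 = ar2_coefficients(rho, f_osc, fs)
        b, a = [1.0], [1.0, -a1, -a2]
        sigma = 1.0 / math.sqrt(ar2_stationary_variance(rho, f_osc, fs))
        if zi is None:
            zi = lfilter_zi(b, a) * 0.0
        seg, zi = lfilter(b, a, sigma * innovations[start:stop], zi=zi)
        out[start:stop] = seg
    return out


def _segments_from_intervals(
    n: int, intervals: list[tuple[int, int]], rho_rest: float, rho_move: float
) -> list[tuple[int, int, float]]:
    """Split [0, n) into constant-rho runs given movement-intention intervals."""
    edges = sorted({0, n, *(max(0, a) for a, _ in intervals),
                    *(min(n, b) for _, b in intervals)})
    segs = []
    for a, b in zip(edges[:-1], edges[1:]):
        if a >= b:
            continue
        inside = any(lo <= a and b <= hi for lo, hi in intervals)
        segs.append((a, b, rho_move if inside else rho_rest))
    return segs


def _erd_gain(
    n: int, onsets_move: np.ndarray, fs: float, cfg: SynthConfig
) -> np.ndarray:
    """Amplitude multiplier over the whole recording (1 outside movement)."""
    gain = np.ones(n)
    t_ramp0 = cfg.erd_ramp_start
    t_hold0, t_hold1 = cfg.erd_hold
    t_rec = cfg.erd_recover
    for onset in onsets_move:
        i0 = onset + int(round(t_ramp0 * fs))
        i1 = onset + int(round(t_hold0 * fs))
        i2 = onset + int(round(t_hold1 * fs))
        i3 = onset + int(round(t_rec * fs))
        ramp_down = np.linspace(1.0, cfg.erd_scale, max(i1 - i0, 1))
        ramp_up = np.linspace(cfg.erd_scale, 1.0, max(i3 - i2, 1))
        sl0 = slice(max(i0, 0), max(i1, 0))
        gain[sl0] = ramp_down[len(ramp_down) - (sl0.stop - sl0.start):]
        gain[max(i1, 0):max(i2, 0)] = cfg.erd_scale
        sl2 = slice(max(i2, 0), min(i3, n))
        gain[sl2] = ramp_up[: sl2.stop - sl2.start]
    return gain


def generate_session(config: SynthConfig):
    """Simulate one session; returns ``(Recording, EventList)``.

    Trials of all configured conditions are laid out in randomized order with
    a uniform 1-1.5 s gap between consecutive epochs, plus lead-in/out.
    Identical config and seed give bit-identical output.
    """
    from .prep import Recording  # local import to avoid cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    pre, post = config.epoch_span

    labels = [c for c in config.conditions
              for _ in range(config.n_trials_per_condition)]
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    gaps = rng.uniform(*config.gap_range, size=len(labels))
    onsets = []
    t = 1.0 + pre  # 1 s lead-in before the first epoch starts
    for k in range(len(labels)):
        onsets.append(int(round(t * fs)))
        t += post + gaps[k] + pre
    n = int(round((t - pre + 1.0) * fs))  # 1 s lead-out
    onsets = np.asarray(onsets, dtype=np.int64)

    move_mask = np.array([lab in MOVEMENT_LABELS for lab in labels])
    move_onsets = onsets[move_mask]
    lo, hi = config.intention_interval
    intervals = [(o + int(round(lo * fs)), o + int(round(hi * fs)))
                 for o in move_onsets]
    segs = _segments_from_intervals(n, intervals, config.rho_rest,
                                    config.rho_move)
    gain = _erd_gain(n, move_onsets, fs, config)

    n_ch = len(config.channel_labels)
    samples = np.empty((n_ch, n))
    shared = None
    if config.mixing != 0.0:
        shared = _piecewise_ar2(
            rng.standard_normal(n), [(0, n, config.rho_rest)],
            config.f_osc, fs,
        )
    tgrid = np.arange(n) / fs
    rho_mu = config.rho_mu if config.rho_mu is not None else config.rho_rest
    for c in range(n_ch):
        x = np.zeros(n)
        if config.ar_scale != 0.0:
            bg = _piecewise_ar2(rng.standard_normal(n), segs, config.f_osc, fs)
            x += config.ar_scale * bg
        if config.mu_scale != 0.0:
            if config.mu_kind == "ar":
                mu = _piecewise_ar2(rng.standard_normal(n),
                                    [(0, n, rho_mu)], config.f_osc, fs)
            else:
                phase = rng.uniform(0.0, 2.0 * math.pi)
                mu = np.sin(2.0 * math.pi * config.f_osc * tgrid + phase)
            x += config.mu_scale * gain * mu
        if shared is not None:
            x += config.mixing * shared
        if config.noise_sd != 0.0:
            x += config.noise_sd * rng.standard_normal(n)
        samples[c] = config.amplitude_uv * x

    rec = Recording(samples=samples, fs=fs,
                    channel_labels=list(config.channel_labels))
    events = EventList(onsets=onsets, labels=labels, fs=fs)
    return rec, events


def null_config(**overrides) -> SynthConfig:
    """A session with no movement effect (same pole radius, no ERD)."""
    base = SynthConfig(**overrides)
    return replace(base, rho_move=base.rho_rest, erd_scale=1.0)
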