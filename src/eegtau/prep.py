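"""Recording I/O, filtering chain, bipolar montage, epoching, windowing.

The preprocessing chain follows the offline analysis convention for
self-paced tapping: 4th-order zero-phase Butterworth filters (0.5 Hz
high-pass, 48-52 Hz band-stop for line noise, 60 Hz low-pass), a
longitudinal bipolar montage over the nine motor channels, 6 s epochs
time-locked to the tap (3 s either side, demeaned per trial), and 1 s
windows stepped by 100 ms whose end-times run from -2.0 s to +3.0 s.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .errors import (
    ConfigurationError,
    EmptySetError,
    FormatError,
    MontageError,
    WindowingError,
)
from .synth import EventList

logger = logging.getLogger(__name__)

#: Canonical capitalisation of 10-20 labels (extend as needed).
_CANONICAL_1020 = {
    name.upper(): name
    for name in (
        "Fp1 Fp2 F7 F3 Fz F4 F8 T3 C3 Cz C4 T4 T5 P3 Pz P4 T6 O1 O2 "
        "FCz AFz A1 A2"
    ).split()
}

DEFAULT_BIPOLAR_PAIRS = (
    ("F3", "C3"),
    ("Fz", "Cz"),
    ("F4", "C4"),
    ("C3", "P3"),
    ("Cz", "Pz"),
    ("C4", "P4"),
)

STANDARD_BANDS = {
    "low": (0.5, 8.0),
    "mu": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "wide": (0.5, 30.0),
}


def normalize_label(label: str) -> str:
    """Map a channel label to its canonical 10-20 capitalisation."""
    return _CANONICAL_1020.get(label.strip().upper(), label.strip())


@dataclass
class Recording:
    """Continuous multichannel signal in microvolts."""

    samples: np.ndarray  # channels x time
    fs: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.fs <= 0:
            raise FormatError("sampling rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise FormatError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        label = normalize_label(label)
        try:
            return self.samples[self.channel_labels.index(label)]
        except ValueError:
            raise MontageError(f"channel {label!r} not in recording") from None


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def validate(self, fs: float) -> None:
        if not (0.0 < self.lo < self.hi):
            raise ConfigurationError(f"invalid band {self.lo}-{self.hi} Hz")
        if self.hi >= fs / 2.0:
            raise ConfigurationError(
                f"band edge {self.hi} Hz at or above Nyquist ({fs / 2} Hz)"
            )


def get_band(band) -> BandDefinition:
    """Accept a band name, (lo, hi) tuple, or BandDefinition."""
    if isinstance(band, BandDefinition):
        return band
    if isinstance(band, str):
        try:
            lo, hi = STANDARD_BANDS[band]
        except KeyError:
            raise ConfigurationError(
                f"unknown band {band!r}; choose from {sorted(STANDARD_BANDS)}"
            ) from None
        return BandDefinition(band, lo, hi)
    lo, hi = band
    return BandDefinition(f"{lo}-{hi}Hz", float(lo), float(hi))


@dataclass(frozen=True)
class WindowSpec:
    """1 s windows stepped by 100 ms; feature at time t uses [t-1, t]."""

    length: float = 1.0
    step: float = 0.1

    def end_times(self, span: tuple[float, float] = (3.0, 3.0)) -> np.ndarray:
        pre, post = span
        t0 = -pre + self.length
        n = int(round((post - t0) / self.step)) + 1
        return np.round(t0 + self.step * np.arange(n), 10)

    def n_samples(self, fs: float) -> int:
        return int(round(self.length * fs))


@dataclass
class SignalWindow:
    """One demeaned 1 s slice of a trial, ending at ``end_time`` s."""

    values: np.ndarray
    fs: float
    end_time: float


@dataclass
class BipolarScheme:
    pairs: tuple[tuple[str, str], ...] = DEFAULT_BIPOLAR_PAIRS

    @property
    def names(self) -> list[str]:
        return [f"{a}-{b}" for a, b in self.pairs]


@dataclass
class TrialSet:
    """Condition-labelled epochs time-locked to tap onset."""

    epochs: np.ndarray  # trial x channel x sample
    time_axis: np.ndarray
    conditions: list[str]
    fs: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trial x channel x sample")
        if self.epochs.shape[0] != len(self.conditions):
            raise ValueError("one condition per trial required")
        if self.epochs.shape[1] != len(self.channel_labels):
            raise ValueError("one label per channel required")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def span(self) -> tuple[float, float]:
        return (-float(self.time_axis[0]),
                float(self.time_axis[-1]) + 1.0 / self.fs)

    def select(self, conditions) -> "TrialSet":
        if isinstance(conditions, str):
            conditions = [conditions]
        idx = [i for i, c in enumerate(self.conditions) if c in conditions]
        if not idx:
            raise EmptySetError(f"no trials with condition in {conditions}")
        return TrialSet(self.epochs[idx], self.time_axis,
                        [self.conditions[i] for i in idx], self.fs,
                        list(self.channel_labels))


# ---------------------------------------------------------------------------
# I/O


def load_recording(path, format: str | None = None,
                   fs: float | None = None) -> Recording:
    """Load an EDF or delimited-text recording.

    Delimited files need a header row of channel labels and a sampling rate,
    given either via ``fs`` or a JSON sidecar ``<path>.json`` with an ``fs``
    key.  Labels are normalised to canonical 10-20 capitalisation; EDF
    voltages are converted to microvolts.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        labels = [normalize_label(ch) for ch in raw.ch_names]
        samples = raw.get_data() * 1e6  # mne returns volts
        rec_fs = float(raw.info["sfreq"])
    elif format == "delimited":
        df = pd.read_csv(path, sep=None, engine="python")
        labels = [normalize_label(str(c)) for c in df.columns]
        samples = df.to_numpy(dtype=np.float64).T
        if fs is None:
            sidecar = path.with_suffix(path.suffix + ".json")
            if sidecar.exists():
                fs = json.loads(sidecar.read_text()).get("fs")
        if fs is None:
            raise FormatError(
                f"no sampling rate for {path}; pass fs= or provide a sidecar"
            )
        rec_fs = float(fs)
    else:
        raise FormatError(f"unknown format {format!r}")
    if len(set(labels)) != len(labels):
        raise FormatError(f"duplicate channel labels in {path}")
    return Recording(samples=samples, fs=rec_fs, channel_labels=labels)


def write_delimited(rec: Recording, path, sep: str = ",") -> None:
    """Write a recording as delimited text plus an ``fs`` JSON sidecar."""
    path = Path(path)
    pd.DataFrame(rec.samples.T, columns=rec.channel_labels).to_csv(
        path, sep=sep, index=False, float_format="%.6f"
    )
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"fs": rec.fs, "units": "uV"})
    )


def write_events(events: EventList, path) -> None:
    """Three-column TSV: onset_sample, onset_seconds, label."""
    df = pd.DataFrame(
        {
            "onset_sample": events.onsets,
            "onset_seconds": events.onsets / events.fs,
            "label": events.labels,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_events(path, fs: float) -> EventList:
    df = pd.read_csv(path, sep="\t")
    if "onset_sample" not in df or "label" not in df:
        raise FormatError(f"{path} lacks onset_sample/label columns")
    return EventList(onsets=df["onset_sample"].to_numpy(np.int64),
                     labels=[str(x) for x in df["label"]], fs=fs)


# ---------------------------------------------------------------------------
# Filtering and montage


def _sos(order: int, cutoff, btype: str, fs: float):
    return butter(order, cutoff, btype=btype, fs=fs, output="sos")


def apply_filters(
    rec: Recording,
    highpass: float = 0.5,
    notch: tuple[float, float] = (48.0, 52.0),
    lowpass: float = 60.0,
) -> Recording:
    """High-pass, 50 Hz band-stop, low-pass; all 4th-order zero-phase.

    Each filter is a 4th-order Butterworth design applied forward-backward
    (zero phase, effective order 8).  The per-channel mean is subtracted
    afterwards.
    """
    if rec.fs <= 2.0 * lowpass:
        raise ConfigurationError(
            f"fs={rec.fs} too low for a {lowpass} Hz low-pass"
        )
    x = rec.samples
    x = sosfiltfilt(_sos(4, highpass, "highpass", rec.fs), x, axis=-1)
    x = sosfiltfilt(_sos(4, list(notch), "bandstop", rec.fs), x, axis=-1)
    x = sosfiltfilt(_sos(4, lowpass, "lowpass", rec.fs), x, axis=-1)
    x = x - x.mean(axis=-1, keepdims=True)
    return Recording(samples=x, fs=rec.fs,
                     channel_labels=list(rec.channel_labels))


def to_bipolar(rec: Recording, scheme: BipolarScheme | None = None) -> Recording:
    """Derive anode-minus-cathode channels named ``A-B`` in scheme order."""
    scheme = scheme or BipolarScheme()
    rows = [rec.channel(a) - rec.channel(b) for a, b in scheme.pairs]
    return Recording(samples=np.vstack(rows), fs=rec.fs,
                     channel_labels=scheme.names)


def bandpass(x: np.ndarray, band, fs: float) -> np.ndarray:
    """4th-order zero-phase Butterworth band-pass along the last axis."""
    b = get_band(band)
    b.validate(fs)
    return sosfiltfilt(_sos(4, [b.lo, b.hi], "bandpass", fs), x, axis=-1)


# ---------------------------------------------------------------------------
# Epoching and windowing


def epoch_trials(
    rec: Recording,
    events: EventList,
    span: tuple[float, float] = (3.0, 3.0),
    transform=None,
) -> TrialSet:
    """Extract demeaned epochs around each event; partial epochs are dropped.

    ``transform`` is an optional pre-epoching hook ``Recording -> Recording``
    (e.g. an ICA-based artefact cleaner); default is identity.
    """
    if transform is not None:
        rec = transform(rec)
    pre, post = span
    n_pre = int(round(pre * rec.fs))
    n_post = int(round(post * rec.fs))
    epochs, conditions = [], []
    for onset, label in zip(events.onsets, events.labels):
        start, stop = onset - n_pre, onset + n_post
        if start < 0 or stop > rec.n_samples:
            logger.warning(
                "dropping event at sample %d (%s): epoch [%d, %d) exceeds "
                "recording of %d samples", onset, label, start, stop,
                rec.n_samples,
            )
            continue
        ep = rec.samples[:, start:stop]
        epochs.append(ep - ep.mean(axis=-1, keepdims=True))
        conditions.append(label)
    if not epochs:
        raise EmptySetError("no event has a full epoch inside the recording")
    time_axis = (np.arange(n_pre + n_post) - n_pre) / rec.fs
    return TrialSet(np.stack(epochs), time_axis, conditions, rec.fs,
                    list(rec.channel_labels))


def sliding_windows(
    epoch: np.ndarray,
    fs: float,
    spec: WindowSpec | None = None,
    span: tuple[float, float] = (3.0, 3.0),
) -> list[SignalWindow]:
    """Cut one single-channel epoch into demeaned 1 s windows.

    The window ending at t covers samples ``[round((t-1+pre)*fs),
    round((t-1+pre)*fs) + round(fs))`` — half-open, constant length.
    """
    spec = spec or WindowSpec()
    epoch = np.asarray(epoch, dtype=np.float64)
    pre = span[0]
    n = spec.n_samples(fs)
    windows = []
    for t in spec.end_times(span):
        start = int(round((t - spec.length + pre) * fs))
        stop = start + n
        if start < 0 or stop > epoch.shape[-1]:
            raise WindowingError(
                f"window ending at {t} s does not fit a {span} epoch"
            )
        vals = epoch[start:stop]
        windows.append(SignalWindow(vals - vals.mean(), fs, float(t)))
    return windows
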