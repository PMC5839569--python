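"""Minimal EDF writer (16-bit, one-second data records).

Covers exactly what the simulator needs: equal sampling rate on every
channel, microvolt physical units, and a final record zero-padded when the
signal length is not a whole number of seconds.  Reading goes through mne's
native EDF reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError

_DIG_MAX = 32767


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field too long: {text!r}")
    return b.ljust(width)


def write_edf(path, samples: np.ndarray, fs: float,
              channel_labels: list[str]) -> None:
    """Write a channels x time array (microvolts) as EDF."""
    samples = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    n_ch, n_t = samples.shape
    if len(channel_labels) != n_ch:
        raise FormatError("one label per channel required")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_rec = int(np.ceil(n_t / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_t] = samples

    # symmetric physical range per channel so zero maps to digital zero;
    # rounded up to 2 decimals so it prints exactly in the 8-char field
    phys_max = np.maximum(np.ceil(np.abs(padded).max(axis=1) * 100) / 100,
                          0.01)
    if np.any(phys_max > 99999.99):
        raise FormatError("signal amplitude too large for the EDF writer")
    scale = _DIG_MAX / phys_max
    digital = np.clip(np.round(padded * scale[:, None]), -_DIG_MAX,
                      _DIG_MAX).astype("<i2")

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate X", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (1 + n_ch)), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_field(lab, 16) for lab in channel_labels),
        b"".join(_field("", 80) for _ in channel_labels),
        b"".join(_field("uV", 8) for _ in channel_labels),
        b"".join(_field(f"{-m:.2f}", 8) for m in phys_max),
        b"".join(_field(f"{m:.2f}", 8) for m in phys_max),
        b"".join(_field(str(-_DIG_MAX), 8) for _ in channel_labels),
        b"".join(_field(str(_DIG_MAX), 8) for _ in channel_labels),
        b"".join(_field("", 80) for _ in channel_labels),
        b"".join(_field(str(spr), 8) for _ in channel_labels),
        b"".join(_field("", 32) for _ in channel_labels),
    ])
    with open(Path(path), "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # record-interleaved: for each 1 s record, all channels in sequence
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
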