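"""Minimal EDF writer.

EDF stores 16-bit samples in fixed-duration records behind an ASCII header.
Only the subset needed to round-trip 10-20 montage recordings is implemented:
one-second records, a common integer sampling rate for all signals, physical
units of microvolts. Files written here are read back with ``mne.io.read_raw_edf``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .recording import EEGRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write ``rec`` to ``path`` as EDF; pads the trailing partial second with zeros."""
    rate = int(round(rec.rate))
    if abs(rate - rec.rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch, n_samp = rec.data.shape
    n_records = int(np.ceil(n_samp / rate))
    padded = np.zeros((n_ch, n_records * rate))
    padded[:, :n_samp] = rec.data

    # Per-channel symmetric physical range; a flat channel still needs a
    # non-degenerate range for the gain to be defined.
    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    phys_min = -phys_max
    gain = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.clip(
        np.rint((padded - phys_min[:, None]) * gain[:, None] + _DIG_MIN),
        _DIG_MIN,
        _DIG_MAX,
    ).astype("<i2")

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(rec.subject_id, 80),
            _ascii(f"condition {rec.condition}", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(str(256 * (1 + n_ch)), 8),
            _ascii("", 44),
            _ascii(str(n_records), 8),
            _ascii("1", 8),
            _ascii(str(n_ch), 4),
        ]
    )

    def field(fmt, width):
        return b"".join(_ascii(fmt(i), width) for i in range(n_ch))

    signal_header = b"".join(
        [
            field(lambda i: rec.channel_labels[i], 16),
            field(lambda i: "", 80),
            field(lambda i: "uV", 8),
            field(lambda i: f"{phys_min[i]:.8g}"[:8], 8),
            field(lambda i: f"{phys_max[i]:.8g}"[:8], 8),
            field(lambda i: str(_DIG_MIN), 8),
            field(lambda i: str(_DIG_MAX), 8),
            field(lambda i: "", 80),
            field(lambda i: str(rate), 8),
            field(lambda i: "", 32),
        ]
    )

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        # records: for each second, each signal's samples consecutively
        for r in range(n_records):
            block = digital[:, r * rate : (r + 1) * rate]
            fh.write(block.tobytes())
    return path
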