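"""EEG recording container and plain-text I/O (CSV, EDF via :mod:`eegnetkit._edf`)."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import MONTAGE_16


@dataclass
class EEGRecording:
    """A channels x samples block of scalp EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal amplitude in microvolts.
    rate : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Ordered 10-20 channel names; must match ``data`` row count.
    subject_id : str
        Subject identifier.
    condition : str
        Condition tag, conventionally ``"pre"`` or ``"post"``.
    """

    data: np.ndarray
    rate: float
    channel_labels: tuple[str, ...] = MONTAGE_16
    subject_id: str = "s00"
    condition: str = "pre"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        unknown = set(self.channel_labels) - set(MONTAGE_16)
        if unknown:
            raise ValueError(f"labels outside the 10-20 montage set: {sorted(unknown)}")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def copy_with(self, **kwargs) -> "EEGRecording":
        return replace(self, **kwargs)


def save_csv(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as samples x channels CSV with a channel-label header."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def load_csv(
    path: str | Path,
    rate: float,
    subject_id: str = "s00",
    condition: str = "pre",
) -> EEGRecording:
    """Read a samples x channels CSV (header = channel labels) into a recording.

    The CSV dialect does not carry the sampling rate; pass it explicitly
    (cohort ledgers written by :mod:`eegnetkit.synthetic` record it).
    """
    df = pd.read_csv(path)
    return EEGRecording(
        data=df.to_numpy().T,
        rate=rate,
        channel_labels=tuple(df.columns),
        subject_id=subject_id,
        condition=condition,
    )


def load_edf(path: str | Path, subject_id: str = "s00", condition: str = "pre") -> EEGRecording:
    """Read an EDF/EDF+ file through MNE, keeping only montage channels, in volts->uV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = [ch.upper() for ch in raw.ch_names]
    keep = [i for i, lab in enumerate(labels) if lab in MONTAGE_16]
    if not keep:
        raise ValueError(f"no 10-20 montage channels found in {path}")
    data = raw.get_data()[keep] * 1e6  # MNE returns volts
    return EEGRecording(
        data=data,
        rate=float(raw.info["sfreq"]),
        channel_labels=tuple(labels[i] for i in keep),
        subject_id=subject_id,
        condition=condition,
    )


def save_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as a plain EDF file (16-bit samples, 1-s records)."""
    from ._edf import write_edf

    return write_edf(rec, path)
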