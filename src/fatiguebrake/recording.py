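"""Multi-channel EEG recording container and file I/O.

The in-memory representation is a plain ``channels x samples`` float array
with a sampling rate and channel labels, mirroring what a consumer headset
(e.g. a 14-channel, 128 Hz EMOTIV) delivers after export. CSV is the primary
interchange format (first column: time in seconds; one column per channel,
header row holds the channel labels). EDF files are read through ``mne``
when that optional dependency is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EEGRecording", "read_eeg_csv", "read_eeg_edf"]


@dataclass
class EEGRecording:
    """A ``channels x samples`` EEG matrix (microvolts) with metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    channel_labels
        Unique label per channel; defaults to ``ch01 .. chNN``.
    preprocessed
        True once the recording has been bandpass filtered / cleaned.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    preprocessed: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("recording needs at least one channel and one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, data: np.ndarray, **kw) -> "EEGRecording":
        """New recording sharing this one's metadata but different samples."""
        return replace(self, data=np.asarray(data, dtype=float), **kw)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        """Write as tidy CSV: time column followed by one column per channel."""
        df = pd.DataFrame(self.data.T, columns=self.channel_labels)
        df.insert(0, "time_s", self.times())
        df.to_csv(path, index=False)


def read_eeg_csv(path: str | Path, preprocessed: bool = False) -> EEGRecording:
    """Load a recording written by :meth:`EEGRecording.to_csv`.

    The sampling rate is recovered from the median spacing of the time column.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("EEG CSV needs a time column plus at least one channel")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("EEG CSV needs at least two samples")
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise ValueError("time column must be strictly increasing")
    labels = list(df.columns[1:])
    data = df.iloc[:, 1:].to_numpy(dtype=float).T
    return EEGRecording(data=data, fs=1.0 / dt, channel_labels=labels,
                        preprocessed=preprocessed)


def read_eeg_edf(path: str | Path) -> EEGRecording:
    """Load an EDF recording via ``mne`` (optional dependency).

    Values are converted from volts (mne's internal unit) to microvolts.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "EDF support requires the optional 'mne' dependency "
            "(pip install fatiguebrake[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )
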