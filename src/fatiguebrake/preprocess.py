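"""EEG cleaning: zero-phase bandpass, channel equalization, artifact rejection.

The cleaning chain mirrors standard resting-EEG practice for consumer
headsets: a 1-30 Hz Butterworth bandpass of order 2 per edge (a 12 dB/octave
slope), applied forward-backward so the net filter is zero phase; bad-channel
removal by a variance-ratio rule against the median channel; transient
artifact removal by z-score thresholding with linear interpolation across the
flagged spans; and finally per-channel z-scoring so every channel carries
equal weight downstream.

The recommended order is ``bandpass_filter -> reject_artifacts ->
normalize_channels``: the variance-ratio rule is only informative while
channels still differ in scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .recording import EEGRecording

__all__ = [
    "PreprocessConfig",
    "ArtifactReport",
    "bandpass_filter",
    "normalize_channels",
    "reject_artifacts",
    "preprocess",
]

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Settings for the cleaning chain.

    ``band_low``/``band_high`` are the bandpass corner frequencies in Hz,
    ``filter_order`` the Butterworth order per band edge (2 = 12 dB/octave).
    ``artifact_z_threshold`` flags samples whose per-channel z-score exceeds
    it; ``bad_channel_variance_ratio`` drops channels whose variance differs
    from the median channel's by more than that factor (either direction).
    """

    band_low: float = 1.0
    band_high: float = 30.0
    filter_order: int = 2
    normalize: bool = True
    artifact_z_threshold: float = 5.0
    bad_channel_variance_ratio: float = 10.0

    def validate(self, fs: float) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError(
                f"need 0 < band_low < band_high, got ({self.band_low}, {self.band_high})"
            )
        if self.band_high >= fs / 2:
            raise ValueError(
                f"band_high={self.band_high} Hz must lie below the Nyquist "
                f"frequency {fs / 2:g} Hz"
            )
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


@dataclass
class ArtifactReport:
    """What :func:`reject_artifacts` did: dropped channels and patched spans."""

    dropped_channels: list[str] = field(default_factory=list)
    interpolated_spans: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_interpolated_samples(self) -> int:
        return sum(b - a + 1 for spans in self.interpolated_spans.values()
                   for a, b in spans)

    def to_json(self, path: str | Path, **extra) -> None:
        payload = {
            "dropped_channels": self.dropped_channels,
            "interpolated_spans": {k: [list(s) for s in v]
                                   for k, v in self.interpolated_spans.items()},
            **extra,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _design_sos(cfg: PreprocessConfig, fs: float) -> np.ndarray:
    return signal.butter(cfg.filter_order, [cfg.band_low, cfg.band_high],
                         btype="bandpass", fs=fs, output="sos")


def bandpass_filter(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Zero-phase Butterworth bandpass of every channel.

    Forward-backward application (``sosfiltfilt``) cancels the phase response
    and doubles the amplitude slope, so a passband tone comes through with
    neither lag nor attenuation while drift and line noise are suppressed.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(rec.fs)
    sos = _design_sos(cfg, rec.fs)
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(out, preprocessed=True)


def normalize_channels(rec: EEGRecording) -> EEGRecording:
    """Z-score each channel to mean 0, sd 1 (population sd).

    Channels with zero variance cannot be scaled; they are set to all zeros
    and a warning is emitted. The transform is idempotent.
    """
    data = rec.data.copy()
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        labels = [rec.channel_labels[i] for i in np.flatnonzero(flat)]
        warnings.warn(f"zero-variance channels left at 0: {labels}", stacklevel=2)
        logger.warning("zero-variance channels left at 0: %s", labels)
    sd[flat] = 1.0
    out = (data - mean) / sd
    out[flat] = 0.0
    return rec.copy_with(out)


def _spans(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean vector as inclusive (start, end)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    return [(int(a), int(b)) for a, b in zip(starts, ends)]


def reject_artifacts(
    rec: EEGRecording, cfg: PreprocessConfig | None = None
) -> tuple[EEGRecording, ArtifactReport]:
    """Drop faulty channels and patch transient artifacts.

    Channels whose variance ratio against the median channel exceeds
    ``bad_channel_variance_ratio`` (or falls below its reciprocal) are
    removed. On the surviving channels, samples with ``|z| >
    artifact_z_threshold`` are replaced by linear interpolation from the
    nearest clean neighbours.
    """
    cfg = cfg or PreprocessConfig()
    variances = rec.data.var(axis=1)
    ref = float(np.median(variances))
    if ref == 0:
        bad = variances > 0  # all-flat reference: only nonflat channels are odd
    else:
        ratio = variances / ref
        bad = (ratio > cfg.bad_channel_variance_ratio) | (
            ratio < 1.0 / cfg.bad_channel_variance_ratio
        )
    keep = ~bad
    if not keep.any():
        raise ValueError("artifact rejection would drop every channel")

    report = ArtifactReport(
        dropped_channels=[rec.channel_labels[i] for i in np.flatnonzero(bad)]
    )
    data = rec.data[keep].copy()
    labels = [rec.channel_labels[i] for i in np.flatnonzero(keep)]

    t = np.arange(data.shape[1])
    for i, label in enumerate(labels):
        x = data[i]
        sd = x.std()
        if sd == 0:
            continue
        z = (x - x.mean()) / sd
        mask = np.abs(z) > cfg.artifact_z_threshold
        if not mask.any():
            continue
        if mask.all():
            # no anchors to interpolate from: flatten to the channel mean
            data[i] = x.mean()
        else:
            data[i, mask] = np.interp(t[mask], t[~mask], x[~mask])
        report.interpolated_spans[label] = _spans(mask)

    return rec.copy_with(data, channel_labels=labels), report


def preprocess(
    rec: EEGRecording, cfg: PreprocessConfig | None = None
) -> tuple[EEGRecording, ArtifactReport]:
    """Full chain: bandpass -> artifact rejection -> (optional) z-scoring."""
    cfg = cfg or PreprocessConfig()
    out = bandpass_filter(rec, cfg)
    out, report = reject_artifacts(out, cfg)
    if cfg.normalize:
        out = normalize_channels(out)
    return out, report
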