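"""Spectral fatigue features: centroid frequency and power spectral entropy.

Both features summarise a per-channel power spectral density estimated with
Welch's method over a restricted band (1-30 Hz by default, matching the
preprocessing filter):

* centroid frequency, ``CF = sum f_i P(f_i) / sum P(f_i)`` - the
  power-weighted mean frequency. Fatigue-related shifts of spectral mass
  toward higher beta frequencies raise CF.
* power spectral entropy, ``PSE = -sum p_i log2 p_i`` with
  ``p_i = P(f_i)/sum P(f_i)`` - the Shannon entropy of the normalized
  spectrum, in bits. A flat (complex) spectrum approaches ``log2 n``; a
  single dominant rhythm approaches 0. Normalizing the PSD first makes the
  entropy scale-invariant and bounded, which the raw-PSD form is not.

Channel selection uses PCA on a sessions-x-channels feature matrix: each of
the leading components nominates the channel with the largest absolute
loading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import EEGRecording

__all__ = [
    "PowerSpectrum",
    "SpectralFeatures",
    "welch_psd",
    "centroid_frequency",
    "power_spectral_entropy",
    "spectral_features",
    "pca_select_channels",
]


class UndefinedFeatureError(ValueError):
    """Raised when a spectral feature is undefined (e.g. all-zero PSD)."""


@dataclass
class PowerSpectrum:
    """Per-channel PSD on a common ascending frequency grid (Hz, power/Hz)."""

    freqs: np.ndarray               # shape (n_bins,)
    psd: np.ndarray                 # shape (n_channels, n_bins), >= 0
    band: tuple[float, float]
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.atleast_2d(np.asarray(self.psd, dtype=float))
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.psd.shape[1] != self.freqs.size:
            raise ValueError("psd and freqs lengths differ")
        if np.any(self.psd < 0):
            raise ValueError("PSD values must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.psd.shape[0]


@dataclass
class SpectralFeatures:
    """One CF (Hz) and PSE (bits) value per channel."""

    cf: np.ndarray
    pse: np.ndarray
    channel_labels: list[str]


def welch_psd(
    rec: EEGRecording,
    window_s: float = 2.0,
    overlap_frac: float = 0.5,
    band: tuple[float, float] = (1.0, 30.0),
) -> PowerSpectrum:
    """Welch-averaged periodogram per channel, restricted to ``band``.

    Hamming windows of ``window_s`` seconds with fractional overlap
    ``overlap_frac``; the retained grid covers ``band`` inclusively.
    """
    nperseg = int(round(window_s * rec.fs))
    if nperseg < 8:
        raise ValueError("window must span at least 8 samples")
    if not 0 <= overlap_frac < 1:
        raise ValueError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    if rec.n_samples < nperseg:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{nperseg}-sample window"
        )
    lo, hi = band
    if not 0 <= lo < hi:
        raise ValueError(f"invalid band {band}")
    freqs, psd = signal.welch(
        rec.data, fs=rec.fs, window="hamming", nperseg=nperseg,
        noverlap=int(round(overlap_frac * nperseg)), axis=1,
    )
    keep = (freqs >= lo) & (freqs <= hi)
    if not keep.any():
        raise ValueError(f"band {band} contains no frequency bins at fs={rec.fs}")
    return PowerSpectrum(freqs=freqs[keep], psd=psd[:, keep], band=(lo, hi),
                         channel_labels=list(rec.channel_labels))


def _channel_psd(spec: PowerSpectrum, channel: int) -> np.ndarray:
    p = spec.psd[channel]
    if not np.any(p > 0):
        raise UndefinedFeatureError(
            f"channel {channel}: all-zero PSD, spectral features undefined"
        )
    return p


def centroid_frequency(spec: PowerSpectrum, channel: int = 0) -> float:
    """Power-weighted mean frequency of one channel's spectrum (Hz)."""
    p = _channel_psd(spec, channel)
    return float(np.sum(spec.freqs * p) / np.sum(p))


def power_spectral_entropy(
    spec: PowerSpectrum, channel: int = 0, normalized: bool = False
) -> float:
    """Shannon entropy of the normalized PSD of one channel.

    Returns bits by default; with ``normalized=True`` the value is divided by
    ``log2(n_bins)`` so it lies in [0, 1] regardless of the grid resolution.
    """
    p = _channel_psd(spec, channel)
    p = p / p.sum()
    nz = p > 0
    h = float(-np.sum(p[nz] * np.log2(p[nz])))
    if normalized:
        n = spec.freqs.size
        h = h / np.log2(n) if n > 1 else 0.0
    return h


def spectral_features(spec: PowerSpectrum, normalized_entropy: bool = False) -> SpectralFeatures:
    """CF and PSE for every channel of a spectrum."""
    cf = np.array([centroid_frequency(spec, i) for i in range(spec.n_channels)])
    pse = np.array([
        power_spectral_entropy(spec, i, normalized=normalized_entropy)
        for i in range(spec.n_channels)
    ])
    return SpectralFeatures(cf=cf, pse=pse, channel_labels=list(spec.channel_labels))


def pca_select_channels(feature_matrix: np.ndarray, k: int = 2) -> list[int]:
    """Pick the ``k`` most representative channels by PCA loadings.

    The sessions-x-channels matrix is column-standardized (constant columns
    are left centered at zero) and decomposed by SVD. For each of the first
    ``k`` principal components the channel with the largest absolute loading
    is returned; ties break toward the lower channel index, and each
    component's sign is fixed by making its largest-magnitude loading
    positive.
    """
    X = np.atleast_2d(np.asarray(feature_matrix, dtype=float))
    n, m = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 2:
        raise ValueError("need at least 2 sessions for PCA")
    if m < k:
        raise ValueError(f"cannot select {k} channels from {m}")

    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = Xc / sd_safe

    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    tol = s[0] * max(n, m) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if rank < k:
        raise ValueError(
            f"feature matrix has rank {rank}, fewer than the requested {k} components"
        )

    chosen: list[int] = []
    for comp in range(k):
        loadings = vt[comp]
        # deterministic sign: largest-|loading| entry made positive
        top = int(np.argmax(np.abs(loadings)))  # argmax takes the first (lowest) index
        if loadings[top] < 0:
            loadings = -loadings
        chosen.append(top)
    return chosen
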