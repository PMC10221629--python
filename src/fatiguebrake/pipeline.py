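"""Glue from raw recordings to per-session feature tables."""

from __future__ import annotations

import pandas as pd

from .features import SpectralFeatures, spectral_features, welch_psd
from .preprocess import PreprocessConfig, preprocess
from .recording import EEGRecording
from .synth import CohortSession

__all__ = ["extract_features", "cohort_feature_table", "feature_wide"]


def extract_features(
    rec: EEGRecording,
    cfg: PreprocessConfig | None = None,
    window_s: float = 2.0,
    overlap_frac: float = 0.5,
    band: tuple[float, float] | None = None,
    normalized_entropy: bool = False,
) -> SpectralFeatures:
    """Clean a recording and extract per-channel CF and PSE.

    One feature value per channel per recording: preprocessing (bandpass,
    artifact rejection, z-scoring), Welch PSD over the retained band
    (defaulting to the filter band), then centroid frequency and spectral
    entropy.
    """
    cfg = cfg or PreprocessConfig()
    band = band or (cfg.band_low, cfg.band_high)
    clean, _ = preprocess(rec, cfg)
    spec = welch_psd(clean, window_s=window_s, overlap_frac=overlap_frac, band=band)
    return spectral_features(spec, normalized_entropy=normalized_entropy)


def cohort_feature_table(
    cohort: list[CohortSession],
    cfg: PreprocessConfig | None = None,
    **feature_kwargs,
) -> pd.DataFrame:
    """Tidy table: one row per (subject, session, channel) with CF/PSE/FSS."""
    rows = []
    for cs in cohort:
        feats = extract_features(cs.recording, cfg, **feature_kwargs)
        for ch, (label, cf, pse) in enumerate(
            zip(feats.channel_labels, feats.cf, feats.pse), start=1
        ):
            rows.append({
                "subject": cs.subject, "session": cs.session,
                "channel": ch, "channel_label": label,
                "cf_hz": float(cf), "pse_bits": float(pse),
                "fss": cs.fss, "latent_level": cs.latent_level,
            })
    return pd.DataFrame(rows)


def feature_wide(table: pd.DataFrame, channels: tuple[int, ...] = (7, 10)) -> pd.DataFrame:
    """Pivot the tidy table to one row per session with cf_chN/pse_chN columns."""
    keep = table[table["channel"].isin(channels)]
    wide = keep.pivot_table(index=["subject", "session", "fss", "latent_level"],
                            columns="channel", values=["cf_hz", "pse_bits"])
    wide.columns = [f"{'cf' if v == 'cf_hz' else 'pse'}_ch{c}" for v, c in wide.columns]
    return wide.reset_index()
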