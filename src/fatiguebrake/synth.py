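"""Synthetic EEG, Stroop-task and fatigue-score data with the coupling
structure the analysis pipeline assumes.

The study data this package analyses are not redistributable, so every
downstream stage is exercised on simulated cohorts instead. The generator is
not a biophysical EEG model; it produces stationary Gaussian signals with a
controlled power spectrum:

* a 1/f^chi background whose exponent flattens as latent fatigue rises
  (raising power spectral entropy), plus
* Gaussian-shaped theta/alpha/beta oscillation bumps whose centers shift up
  and whose beta weight grows with fatigue (raising the spectral centroid).

Stroop reaction times are shifted-lognormal, truncated by the 2 s response
window, with an additive incongruency cost and a linear fatigue slowdown.
Subjective fatigue labels are the latent level plus Gaussian observer noise,
snapped to the half-point grid of a 5-point (0-4) fatigue severity scale.

All generators require an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import EEGRecording

__all__ = [
    "FatigueProfile",
    "StroopTrial",
    "CohortSession",
    "generate_eeg",
    "generate_stroop_session",
    "generate_cohort",
    "stroop_summary",
    "fss_label",
    "inject_transient",
    "write_cohort",
]

_RT_SHIFT_MS = 300.0     # shifted-lognormal location (non-decision time)
_RT_LOG_SD = 0.2         # lognormal shape on the decision component
_RESPONSE_WINDOW_MS = 2000.0
_N_COLORS = 4            # 4 words x 4 colors = 16 stimulus combinations


@dataclass(frozen=True)
class FatigueProfile:
    """Latent fatigue level and the effect sizes it drives.

    ``level`` lives on the 0-4 subjective-scale range. ``cf_gain`` (Hz per
    fatigue unit) sets how far the oscillation peaks migrate upward;
    ``pse_gain`` (bits per fatigue unit) scales how much the background
    spectrum flattens. ``rt_base_ms`` is the mean congruent reaction time at
    level 0, ``rt_fatigue_slope_ms`` the added mean RT per fatigue unit and
    ``stroop_cost_ms`` the mean incongruent-congruent difference. Defaults
    are sized to the session summaries of a 12-participant Stroop study
    (congruent means near 850 ms, Stroop effects near 230 ms).
    """

    level: float = 0.0
    cf_gain: float = 0.4
    pse_gain: float = 0.05
    rt_base_ms: float = 850.0
    rt_fatigue_slope_ms: float = 60.0
    stroop_cost_ms: float = 230.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 4.0:
            raise ValueError(f"fatigue level must lie in [0, 4], got {self.level}")
        for name in ("cf_gain", "pse_gain", "stroop_cost_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rt_base_ms <= _RT_SHIFT_MS:
            raise ValueError(f"rt_base_ms must exceed the {_RT_SHIFT_MS} ms shift")
        if self.rt_fatigue_slope_ms < 0:
            raise ValueError("rt_fatigue_slope_ms must be >= 0")

    def at_level(self, level: float) -> "FatigueProfile":
        return replace(self, level=float(level))


@dataclass(frozen=True)
class StroopTrial:
    """One trial: condition, reaction time, and whether it beat the window."""

    congruent: bool
    rt_ms: float
    responded: bool

    def __post_init__(self) -> None:
        if self.rt_ms <= 0:
            raise ValueError("rt_ms must be positive")


def _target_psd(freqs: np.ndarray, profile: FatigueProfile) -> np.ndarray:
    """Target one-sided PSD shape (arbitrary units) at the profile's level."""
    lv = profile.level
    # background: 1/f^chi, flattening with fatigue (drives entropy upward)
    chi = max(0.2, 1.0 - 0.12 * lv * (profile.pse_gain / 0.05))
    f_safe = np.maximum(freqs, 0.5)
    psd = 0.6 * f_safe ** (-chi)
    # oscillations: (center Hz, weight, sigma Hz); centers migrate up and
    # beta weight grows with fatigue (drives the centroid upward)
    g = profile.cf_gain
    bumps = (
        (5.5, 1.0, 1.5),
        (10.0 + 0.5 * g * lv, max(0.5, 1.3 - 0.1 * lv), 1.5),
        (19.0 + g * lv, 0.45 + 0.22 * lv, 3.0),
    )
    for c, w, s in bumps:
        psd = psd + w * np.exp(-0.5 * ((freqs - c) / s) ** 2)
    return psd


def generate_eeg(
    profile: FatigueProfile,
    n_channels: int = 14,
    fs: float = 128.0,
    duration: float = 60.0,
    seed: int | None = None,
) -> EEGRecording:
    """Simulate a multi-channel recording at the profile's fatigue level.

    Each channel is an independent stationary Gaussian signal synthesized in
    the frequency domain (random phases on the target amplitude spectrum),
    scaled to 30 uV rms. In expectation over seeds, the extracted centroid
    frequency and spectral entropy increase monotonically with
    ``profile.level`` whenever the profile gains are non-negative.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required for reproducibility")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")
    if duration < 4.0:
        raise ValueError("duration must be at least 4 s")
    top = 19.0 + profile.cf_gain * profile.level + 3 * 3.0  # beta center + 3 sigma
    if fs <= 2 * top:
        raise ValueError(
            f"fs={fs} Hz cannot represent oscillations up to {top:.1f} Hz"
        )

    rng = np.random.default_rng(seed)
    n = int(round(fs * duration))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.sqrt(_target_psd(freqs, profile))
    amp[0] = 0.0  # no DC

    data = np.empty((n_channels, n), dtype=float)
    for ch in range(n_channels):
        re = rng.standard_normal(freqs.size)
        im = rng.standard_normal(freqs.size)
        coeff = amp * (re + 1j * im) / np.sqrt(2.0)
        coeff[0] = 0.0
        if n % 2 == 0:
            coeff[-1] = amp[-1] * re[-1]  # Nyquist bin must be real
        x = np.fft.irfft(coeff, n=n)
        rms = x.std()
        data[ch] = 30.0 * x / rms if rms > 0 else x
    labels = [f"ch{i + 1:02d}" for i in range(n_channels)]
    return EEGRecording(data=data, fs=float(fs), channel_labels=labels)


def inject_transient(
    rec: EEGRecording, channel: int, start: int, width: int, amplitude_uv: float
) -> EEGRecording:
    """Return a copy with a square artifact planted on one channel.

    Intended for exercising artifact rejection; not a physiological model.
    """
    if width < 1 or not 0 <= start < rec.n_samples:
        raise ValueError("invalid transient placement")
    data = rec.data.copy()
    data[channel, start:start + width] += amplitude_uv
    return rec.copy_with(data)


def generate_stroop_session(
    profile: FatigueProfile, n_trials: int = 40, seed: int | None = None
) -> list[StroopTrial]:
    """Simulate one Stroop set of ``n_trials`` trials.

    Stimuli are drawn uniformly from the 16 word/color combinations (so a
    quarter of trials are congruent in expectation). Reaction times are
    shifted-lognormal with mean ``rt_base + slope*level`` plus
    ``stroop_cost`` on incongruent trials; draws beyond the 2 s response
    window are recorded as non-responses.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required for reproducibility")
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(seed)
    words = rng.integers(0, _N_COLORS, size=n_trials)
    colors = rng.integers(0, _N_COLORS, size=n_trials)
    trials = []
    for w, c in zip(words, colors):
        congruent = bool(w == c)
        mean_rt = profile.rt_base_ms + profile.rt_fatigue_slope_ms * profile.level
        if not congruent:
            mean_rt += profile.stroop_cost_ms
        mu_log = np.log(mean_rt - _RT_SHIFT_MS) - _RT_LOG_SD**2 / 2
        rt = _RT_SHIFT_MS + rng.lognormal(mu_log, _RT_LOG_SD)
        trials.append(StroopTrial(congruent=congruent, rt_ms=float(rt),
                                  responded=bool(rt <= _RESPONSE_WINDOW_MS)))
    return trials


def stroop_summary(trials: list[StroopTrial]) -> dict[str, float]:
    """Mean congruent/incongruent RT (responded trials only) and their gap."""
    cong = [t.rt_ms for t in trials if t.congruent and t.responded]
    incong = [t.rt_ms for t in trials if not t.congruent and t.responded]
    cm = float(np.mean(cong)) if cong else np.nan
    im = float(np.mean(incong)) if incong else np.nan
    return {"congruent_mean_ms": cm, "incongruent_mean_ms": im,
            "stroop_effect_ms": im - cm}


def fss_label(level: float, noise_sd: float, rng: np.random.Generator) -> float:
    """Observed fatigue score: noisy latent level snapped to {0, 0.5, ..., 4}."""
    noisy = level + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    return float(np.clip(np.round(2.0 * noisy) / 2.0, 0.0, 4.0))


@dataclass
class CohortSession:
    """Everything simulated for one subject-session."""

    subject: int
    session: int
    latent_level: float
    fss: float
    recording: EEGRecording
    trials: list[StroopTrial] = field(repr=False)


def generate_cohort(
    n_subjects: int = 12,
    n_sessions: int = 5,
    profile_schedule: dict[int, float] | None = None,
    seed: int | None = None,
    base_profile: FatigueProfile | None = None,
    duration: float = 60.0,
    fs: float = 128.0,
    n_channels: int = 14,
    n_trials: int = 40,
    fss_noise_sd: float = 0.5,
) -> list[CohortSession]:
    """Simulate a full study: EEG + Stroop trials + fatigue label per session.

    Latent fatigue accumulates across sessions. By default each subject
    starts at a baseline drawn from U(0, 0.5) and gains a subject-specific
    U(0.35, 0.75) per session, so fifth-set levels land near 2-3 as in a
    five-set fatigue-induction protocol. ``profile_schedule`` overrides the
    accumulation with explicit per-session increments added to the baseline.
    With ``fss_noise_sd=0`` the label is exactly the clamped latent level
    snapped to the half-point grid.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required for reproducibility")
    if n_subjects < 1 or n_sessions < 1:
        raise ValueError("n_subjects and n_sessions must be >= 1")
    base_profile = base_profile or FatigueProfile()

    root = np.random.SeedSequence(seed)
    subj_seqs = root.spawn(n_subjects)
    sessions: list[CohortSession] = []
    for i, sseq in enumerate(subj_seqs, start=1):
        subj_rng = np.random.default_rng(sseq)
        baseline = subj_rng.uniform(0.0, 0.5)
        rate = subj_rng.uniform(0.35, 0.75)
        child = sseq.spawn(n_sessions)
        for s, cseq in enumerate(child, start=1):
            if profile_schedule is not None:
                level = baseline + profile_schedule.get(s, 0.0)
            else:
                level = baseline + rate * (s - 1)
            level = float(np.clip(level, 0.0, 4.0))
            eeg_seed, stroop_seed = (int(x) for x in cseq.generate_state(2))
            profile = base_profile.at_level(level)
            rec = generate_eeg(profile, n_channels=n_channels, fs=fs,
                               duration=duration, seed=eeg_seed)
            trials = generate_stroop_session(profile, n_trials=n_trials,
                                             seed=stroop_seed)
            label_rng = np.random.default_rng(cseq.generate_state(3)[2])
            sessions.append(CohortSession(
                subject=i, session=s, latent_level=level,
                fss=fss_label(level, fss_noise_sd, label_rng),
                recording=rec, trials=trials,
            ))
    return sessions


def cohort_frame(cohort: list[CohortSession]) -> pd.DataFrame:
    """Tidy per-session summary: RT means, Stroop effect and fatigue score."""
    rows = []
    for cs in cohort:
        summ = stroop_summary(cs.trials)
        rows.append({"subject": cs.subject, "session": cs.session,
                     "latent_level": cs.latent_level, **summ, "fss": cs.fss})
    return pd.DataFrame(rows)


def write_cohort(cohort: list[CohortSession], outdir: str | Path) -> Path:
    """Write per-session EEG CSVs plus a tidy ``sessions.csv`` summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cs in cohort:
        cs.recording.to_csv(outdir / f"sub{cs.subject:02d}_ses{cs.session}.csv")
    cohort_frame(cohort).to_csv(outdir / "sessions.csv", index=False)
    return outdir
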