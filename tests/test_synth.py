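"""Generator contracts: determinism, effect directions, label grids."""

import numpy as np
import pytest

from fatiguebrake import (
    FatigueProfile,
    fss_label,
    generate_cohort,
    generate_eeg,
    generate_stroop_session,
    spectral_features,
    stroop_summary,
    welch_psd,
)
from fatiguebrake.pipeline import extract_features


class TestGenerateEEG:
    def test_shape_and_metadata(self):
        rec = generate_eeg(FatigueProfile(), n_channels=14, fs=128.0,
                           duration=60.0, seed=1)
        assert rec.data.shape == (14, 7680)
        assert rec.fs == 128.0
        assert len(set(rec.channel_labels)) == 14

    def test_same_seed_bit_identical(self):
        a = generate_eeg(FatigueProfile(), 4, 128.0, 8.0, seed=1)
        b = generate_eeg(FatigueProfile(), 4, 128.0, 8.0, seed=1)
        assert np.array_equal(a.data, b.data)
        c = generate_eeg(FatigueProfile(), 4, 128.0, 8.0, seed=2)
        assert not np.array_equal(a.data, c.data)

    @pytest.mark.parametrize("kwargs", [
        {"seed": None},
        {"duration": 0.0, "seed": 1},
        {"duration": 2.0, "seed": 1},
        {"fs": -1.0, "seed": 1},
        {"fs": 40.0, "seed": 1},      # cannot represent the beta band
        {"n_channels": 0, "seed": 1},
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        defaults = dict(n_channels=4, fs=128.0, duration=8.0)
        defaults.update(kwargs)
        with pytest.raises(ValueError):
            generate_eeg(FatigueProfile(), **defaults)

    def test_cf_and_pse_rise_with_fatigue(self):
        """Ensemble-mean extracted CF and PSE increase with the latent level,
        using the feature pipeline itself as the measurement oracle."""
        means = {}
        for level in (0.0, 2.0, 4.0):
            cf, pse = [], []
            for seed in range(20):
                rec = generate_eeg(FatigueProfile().at_level(level), 2, 128.0,
                                   8.0, seed=seed)
                feats = extract_features(rec)
                cf.append(feats.cf.mean())
                pse.append(feats.pse.mean())
            means[level] = (np.mean(cf), np.mean(pse))
        assert means[0.0][0] < means[2.0][0] < means[4.0][0]
        assert means[0.0][1] < means[2.0][1] < means[4.0][1]

    def test_spectrum_is_band_limited_noise(self, short_eeg):
        spec = welch_psd(short_eeg, band=(1.0, 60.0))
        feats = spectral_features(spec)
        assert np.all(feats.cf > 1.0) and np.all(feats.cf < 30.0)


class TestStroop:
    def test_trial_count_and_determinism(self):
        trials = generate_stroop_session(FatigueProfile(), 40, seed=7)
        assert len(trials) == 40
        again = generate_stroop_session(FatigueProfile(), 40, seed=7)
        assert [t.rt_ms for t in trials] == [t.rt_ms for t in again]

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_stroop_session(FatigueProfile(), -3, seed=1)
        with pytest.raises(ValueError):
            generate_stroop_session(FatigueProfile(), 40)

    def test_congruent_fraction_matches_16_combination_design(self):
        trials = [t for s in range(50)
                  for t in generate_stroop_session(FatigueProfile(), 40, seed=s)]
        frac = np.mean([t.congruent for t in trials])
        assert abs(frac - 0.25) < 0.03  # 4 of the 16 word/color pairs match

    def test_zero_cost_gives_null_effect(self):
        profile = FatigueProfile(stroop_cost_ms=0.0)
        effects = [stroop_summary(generate_stroop_session(profile, 40, seed=s))
                   ["stroop_effect_ms"] for s in range(100)]
        assert abs(np.mean(effects)) < 15.0

    def test_effect_matches_configured_cost(self):
        """Profile tuned to 790/1118 ms means yields a ~328 ms Stroop effect."""
        profile = FatigueProfile(rt_base_ms=790.0, stroop_cost_ms=328.0,
                                 rt_fatigue_slope_ms=0.0)
        effects = [stroop_summary(generate_stroop_session(profile, 40, seed=s))
                   ["stroop_effect_ms"] for s in range(200)]
        assert abs(np.mean(effects) - 328.0) < 20.0

    def test_rts_grow_with_fatigue(self):
        lo = [t.rt_ms for s in range(50) for t in
              generate_stroop_session(FatigueProfile().at_level(0.0), 40, seed=s)]
        hi = [t.rt_ms for s in range(50) for t in
              generate_stroop_session(FatigueProfile().at_level(3.0), 40, seed=s)]
        assert np.mean(hi) > np.mean(lo) + 100.0

    def test_response_window_rule(self):
        profile = FatigueProfile(rt_base_ms=1900.0, stroop_cost_ms=400.0)
        trials = [t for s in range(20)
                  for t in generate_stroop_session(profile, 40, seed=s)]
        assert any(not t.responded for t in trials)
        for t in trials:
            assert t.responded == (t.rt_ms <= 2000.0)


class TestLabelsAndCohort:
    def test_fss_on_half_point_grid(self):
        rng = np.random.default_rng(0)
        labels = [fss_label(rng.uniform(0, 4), 0.5, rng) for _ in range(200)]
        assert all(0 <= v <= 4 and (2 * v) == int(2 * v) for v in labels)

    def test_noise_free_label_is_clamped_latent(self):
        rng = np.random.default_rng(0)
        assert fss_label(1.5, 0.0, rng) == 1.5
        assert fss_label(5.7, 0.0, rng) == 4.0

    def test_cohort_counts_and_determinism(self):
        kw = dict(n_subjects=3, n_sessions=2, duration=4.0, n_channels=2, seed=3)
        cohort = generate_cohort(**kw)
        assert len(cohort) == 6
        assert {(c.subject, c.session) for c in cohort} == {
            (i, s) for i in (1, 2, 3) for s in (1, 2)}
        again = generate_cohort(**kw)
        assert all(np.array_equal(a.recording.data, b.recording.data)
                   and a.fss == b.fss for a, b in zip(cohort, again))

    def test_schedule_controls_latent_level(self):
        cohort = generate_cohort(n_subjects=2, n_sessions=3,
                                 profile_schedule={1: 0.0, 2: 1.0, 3: 2.0},
                                 duration=4.0, n_channels=1, seed=5,
                                 fss_noise_sd=0.0)
        for c in cohort:
            base = next(x.latent_level for x in cohort
                        if x.subject == c.subject and x.session == 1)
            assert c.latent_level == pytest.approx(base + (c.session - 1) * 1.0)

    def test_latent_level_recoverable_from_features(self):
        """Pooled over cohorts, extracted CF tracks the latent fatigue level."""
        from scipy.stats import pearsonr

        levels, cfs = [], []
        for seed in range(5):
            cohort = generate_cohort(n_subjects=6, n_sessions=3, duration=8.0,
                                     n_channels=2, seed=seed)
            for c in cohort:
                feats = extract_features(c.recording)
                levels.append(c.latent_level)
                cfs.append(feats.cf.mean())
        assert pearsonr(levels, cfs).statistic > 0.5
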