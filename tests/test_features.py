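"""Spectral feature math: centroid frequency, spectral entropy, PCA picks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fatiguebrake import (
    EEGRecording,
    PowerSpectrum,
    centroid_frequency,
    pca_select_channels,
    power_spectral_entropy,
    welch_psd,
)
from fatiguebrake.features import UndefinedFeatureError


def make_spectrum(freqs, psd):
    return PowerSpectrum(freqs=np.asarray(freqs, float),
                         psd=np.atleast_2d(np.asarray(psd, float)),
                         band=(float(freqs[0]), float(freqs[-1])),
                         channel_labels=["ch01"])


class TestWelch:
    def test_peak_at_tone_frequency(self, sine_recording):
        spec = welch_psd(sine_recording, window_s=2.0, band=(1.0, 30.0))
        peak = spec.freqs[np.argmax(spec.psd[0])]
        assert abs(peak - 10.0) <= 0.5

    def test_white_noise_band_power_matches_variance(self):
        """Band-integrated PSD recovers the variance share of the band."""
        fs, band = 128.0, (1.0, 30.0)
        shares = []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(int(32 * fs))
            rec = EEGRecording(np.atleast_2d(x), fs)
            spec = welch_psd(rec, window_s=2.0, band=band)
            df = spec.freqs[1] - spec.freqs[0]
            shares.append(np.sum(spec.psd[0]) * df / x.var())
        expected = (band[1] - band[0]) / (fs / 2)
        assert np.mean(shares) == pytest.approx(expected, rel=0.10)

    def test_zero_signal_zero_psd(self):
        rec = EEGRecording(np.zeros((1, 1024)), 128.0)
        spec = welch_psd(rec)
        assert np.all(spec.psd == 0.0)
        with pytest.raises(UndefinedFeatureError):
            centroid_frequency(spec, 0)
        with pytest.raises(UndefinedFeatureError):
            power_spectral_entropy(spec, 0)

    def test_too_short_recording_rejected(self):
        rec = EEGRecording(np.random.default_rng(0).standard_normal((1, 100)), 128.0)
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(rec, window_s=2.0)


# hand-evaluated expected values for the two feature formulas
CF_CASES = [
    ([5.0, 10.0, 15.0], [0.0, 2.0, 0.0], 10.0),            # delta spectrum
    ([2.0, 4.0, 6.0, 8.0], [1.0, 1.0, 1.0, 1.0], 5.0),     # uniform -> plain mean
    ([10.0, 20.0], [1.0, 3.0], 17.5),                       # (10*1 + 20*3)/4
]
PSE_CASES = [
    ([5.0, 10.0, 15.0], [0.0, 2.0, 0.0], 0.0),                       # delta -> 0 bits
    (list(range(1, 9)), [3.0] * 8, 3.0),                             # uniform 8 -> log2 8
    ([1.0, 2.0, 3.0], [0.5, 0.25, 0.25], 1.5),                       # hand Shannon sum
]


class TestFeatureMath:
    @pytest.mark.parametrize("freqs,psd,expected", CF_CASES)
    def test_centroid_hand_examples(self, freqs, psd, expected):
        assert centroid_frequency(make_spectrum(freqs, psd)) == pytest.approx(
            expected, abs=1e-12)

    @pytest.mark.parametrize("freqs,psd,expected", PSE_CASES)
    def test_entropy_hand_examples(self, freqs, psd, expected):
        assert power_spectral_entropy(make_spectrum(freqs, psd)) == pytest.approx(
            expected, abs=1e-12)

    def test_normalized_entropy_unit_interval(self):
        spec = make_spectrum(list(range(1, 9)), [3.0] * 8)
        assert power_spectral_entropy(spec, normalized=True) == pytest.approx(1.0)

    @given(scale=st.floats(1e-6, 1e6),
           psd=st.lists(st.floats(0.0, 1e3), min_size=2, max_size=12))
    @settings(max_examples=60, derandomize=True)
    def test_scale_invariance_and_bounds(self, scale, psd):
        psd = np.asarray(psd)
        if not np.any(psd > 0):
            psd[0] = 1.0
        freqs = np.arange(1.0, 1.0 + len(psd))
        spec = make_spectrum(freqs, psd)
        scaled = make_spectrum(freqs, psd * scale)
        cf = centroid_frequency(spec)
        pse = power_spectral_entropy(spec)
        assert centroid_frequency(scaled) == pytest.approx(cf, rel=1e-9)
        assert power_spectral_entropy(scaled) == pytest.approx(pse, abs=1e-9)
        assert freqs[0] <= cf <= freqs[-1]          # convex hull of the grid
        assert -1e-12 <= pse <= np.log2(len(psd)) + 1e-12


class TestPCASelection:
    def test_single_varying_channel(self):
        rng = np.random.default_rng(0)
        X = np.zeros((10, 6))
        X[:, 3] = rng.standard_normal(10)
        assert pca_select_channels(X, k=1) == [3]

    def test_two_planted_factors_recovered(self):
        """Two orthogonal latent sources, each carried nearly purely by one
        dominant channel (2 resp. 5) and partially by satellite channels,
        are traced back to their dominant channels. The groups differ in
        strength so the leading eigenvalues are well separated (equal-power
        groups would leave the component pair free to rotate), and each
        group spans three channels (within a standardized two-channel group
        the loadings are equal by symmetry, so no dominant channel exists)."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            f1, f2 = rng.standard_normal((2, n))
            X = np.empty((n, 7))
            X[:, 2] = f1 + 0.1 * rng.standard_normal(n)
            X[:, 0] = 0.7 * f1 + 0.7 * rng.standard_normal(n)
            X[:, 1] = 0.7 * f1 + 0.7 * rng.standard_normal(n)
            X[:, 4] = 0.7 * f1 + 0.7 * rng.standard_normal(n)
            X[:, 5] = f2 + 0.1 * rng.standard_normal(n)
            X[:, 3] = 0.5 * f2 + 0.87 * rng.standard_normal(n)
            X[:, 6] = 0.5 * f2 + 0.87 * rng.standard_normal(n)
            if pca_select_channels(X, k=2) == [2, 5]:
                hits += 1
        assert hits >= 18

    def test_full_rank_selection_exhausts_channels(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 5))
        picks = pca_select_channels(X, k=5)
        assert len(picks) == 5

    def test_rank_deficiency_reported(self):
        X = np.outer(np.arange(8.0), np.ones(4))  # rank 1
        with pytest.raises(ValueError, match="rank 1"):
            pca_select_channels(X, k=2)

    def test_matches_sklearn_loadings(self):
        """Independent oracle: sklearn PCA's top-loading channels agree."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 6)) * rng.uniform(0.5, 3.0, size=6)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        expected = [int(np.argmax(np.abs(c))) for c in PCA(n_components=3).fit(Z).components_]
        assert pca_select_channels(X, k=3) == expected

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((25, 5)) * np.array([3.0, 0.2, 1.0, 0.5, 2.0])
        perm = np.array([4, 2, 0, 1, 3])
        picks = pca_select_channels(X, k=2)
        picks_perm = pca_select_channels(X[:, perm], k=2)
        assert [int(perm[i]) for i in picks_perm] == picks
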