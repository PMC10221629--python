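# Methods

This note records the models, conventions and deliberately made choices
behind `fatiguebrake`, in the order of the pipeline.

## Signal model of the synthetic EEG

`synth.generate_eeg` produces stationary Gaussian signals with a controlled
one-sided power spectrum, synthesized in the frequency domain (target
amplitude spectrum × complex Gaussian phases, inverse real FFT, scaled to
30 µV rms). The target spectrum is

- a `1/f^χ` background with `χ = max(0.2, 1 − 0.12·level·(pse_gain/0.05))`
  — flattening with latent fatigue raises spectral entropy;
- three Gaussian oscillation bumps (theta 5.5 Hz, alpha 10 Hz, beta 19 Hz,
  σ = 1.5/1.5/3 Hz). With fatigue `level ∈ [0, 4]`, the alpha and beta
  centers migrate up by `0.5·cf_gain·level` and `cf_gain·level` Hz and the
  beta weight grows from 0.45 by 0.22 per level, shifting spectral mass
  upward and raising the centroid.

The gains are *directional* knobs, not calibrated physiology: they
guarantee that, in expectation over seeds, extracted CF and PSE are
monotone in the latent level whenever the gains are non-negative (verified
by ensemble tests using the feature pipeline itself as the measurement).
What the generator deliberately does not emulate: volume conduction and
channel covariance structure, eye-blink/EMG artifacts (a square-transient
injector exists purely to exercise artifact rejection), non-stationarity
within a session, and any event-locking to Stroop stimuli. Passing tests on
this generator therefore demonstrate the *pipeline's* correctness and the
recoverability of a planted monotone coupling — not that real EEG behaves
this way.

Stroop reaction times are shifted lognormal: `rt = 300 ms + LogNormal`
with log-sd 0.2 and mean `rt_base + slope·level (+ cost if incongruent)`;
draws beyond the 2 s response window are recorded as non-responses. The
stimulus is drawn uniformly from the 16 word/color combinations (so 1/4 of
trials are congruent in expectation). Trial-level RT distributions are
unconstrained by the study (which prints only session means); the lognormal
is a standard right-skewed choice. Defaults (`rt_base` 850 ms, slope
60 ms/level, cost 230 ms) are sized to the printed session summaries.
Subjective fatigue labels are the latent level plus N(0, 0.5²) observer
noise, snapped to the half-point grid on [0, 4] — reproducing the
half-point scores seen in practice on a nominally integer 5-point scale.

Cohort latent fatigue rises linearly across sessions with a per-subject
baseline U(0, 0.5) and rate U(0.35, 0.75) per session, mirroring a
five-set fatigue-induction protocol in which fifth-set scores exceed
first-set scores for nearly all subjects. All generators require an
explicit seed and are bit-reproducible via `numpy.random.SeedSequence`
spawning.

## Preprocessing

- Bandpass: Butterworth of order 2 per band edge (the standard reading of a
  "12 dB/octave" slope), 1–30 Hz, applied forward–backward
  (`scipy.signal.sosfiltfilt`) for zero phase; the effective amplitude
  slope is doubled. Edge handling uses scipy's default odd-extension
  padding; a literal 3×order (= 6 samples) pad would be far too short for a
  1 Hz edge at 128 Hz.
- Artifact rejection: channels whose variance differs from the median
  channel's by more than 10× (either direction) are dropped; samples with
  per-channel |z| > 5 are patched by linear interpolation. This replaces
  ICA denoising on purpose: ICA unmixing is not reproducible from a
  published description and is unnecessary for exercising the downstream
  mathematics, whereas the threshold rules are fully specified and
  testable.
- Equalization: per-channel z-scoring (idempotent; constant channels are
  zeroed with a warning). The recommended order is *filter → reject →
  normalize*, because the variance-ratio rule is uninformative once every
  channel has unit variance. No re-referencing is attempted: the reference
  montage of the source device is unspecified, and per-channel z-scoring is
  the neutral choice.

## Features

PSD: Welch with 2 s Hamming windows, 50% overlap, restricted to the filter
band. Centroid frequency is the power-weighted mean frequency; it is
invariant to PSD scaling and lies in the convex hull of the retained grid.
Spectral entropy normalizes the PSD to a probability distribution *before*
the entropy sum: the unnormalized form is scale- and unit-dependent and
unbounded, while the normalized form is scale-invariant and bounded by
`[0, log₂ n]`. An optional `normalized=True` switch divides by `log₂ n`,
matching feature tables whose entropy values lie in (0, 1); the packaged
study features are consumed as printed, never re-derived (the raw EEG
behind them is unavailable).

PCA channel selection column-standardizes the matrix, takes the SVD, and
for each leading component nominates the channel with the largest absolute
loading (first index on ties; component sign fixed by making that loading
positive). Note a structural property of standardized PCA exploited in the
tests: within a two-channel correlated group the loadings are equal by
symmetry, so a "dominant channel" is only identifiable in groups of three
or more channels, and two equally strong factors leave their component pair
free to rotate.

## Correlation analysis

Pearson r with the exact two-tailed small-sample p-value
(`t = r√(n−2)/√(1−r²)` on n−2 df, via `scipy.stats.pearsonr`), validated
against a 10⁵-draw permutation null in the tests. No multiple-testing
correction is applied, matching how such feature screens are reported. The
full 5×5 matrix (CF/PSE of channels 7 and 10 plus the fatigue score) is
presented with r below and p above the diagonal.

## Ridge model

The analytic solve supports two orthogonal conventions:

- `standardize`: z-score features and response before solving;
- `loss`: `"sum"` solves `(XᵀX + αI)β = Xᵀy`; `"mean"` solves
  `(XᵀX/n + αI)β = Xᵀy/n` (α penalizing the mean rather than summed
  squared error). The two differ only by rescaling α by n — but a published
  α is meaningless without knowing which loss normalization produced it.

The intercept is never penalized; it is recovered from training means. This
deviates from the bare normal-equation form (which would shrink the
intercept too) because the loss function it derives from separates the
intercept from the penalty sum.

**Why the reproduction defaults to raw features + mean loss.** The printed
study model at α = 0.1 has slope vector (0.86, 0.06, 0.15). On the printed
feature table, z-scored ridge at α = 0.1 yields (0.745, 0.030, 0.158) —
the leading coefficient is far off — whereas the mean-loss solve on raw
features yields (0.892, 0.082, 0.127) on the 22 model-construction rows
(and (0.842, 0.080, 0.130) on all 24), matching the printed pattern. The
printed intercept (−0.04) is inconsistent with *any* raw-feature
convention (the raw intercept is ≈ −5.4, and the printed slopes applied to
raw features would predict scores near 6 on a 0–4 scale), so it is shown
side-by-side but never asserted. The reproduction report always prints
both conventions.

Cross-validation shuffles rows with an explicit seed, splits into k
near-equal folds, re-estimates all scaling on the training folds only, and
averages the fold errors. The "average validation error" is reported as
MAE by default (with RMSE and MSE alongside): at n = 22, five-fold CV MAE
averaged over 100 fold shuffles is ≈ 0.365 fatigue points, consistent with
the printed 0.36, while MSE (0.22) and RMSE (0.44) are not. α selection
minimizes CV MSE over a grid with a shared fold assignment; ties break to
the smaller α. The predicted-vs-actual correlation is computed both
in-sample (0.889 at n = 22) and from pooled out-of-fold predictions
(0.861 averaged over 100 shuffles); the cross-validated variant is the one
reported against the printed 0.83, which appears in the study's
cross-validation evaluation.

**Exclusion subsets.** The flagged participant (negative Stroop effects in
both sessions) is dropped *for model construction* (subject mode, n = 22),
as the study states. The printed correlations, however, are recovered
almost exactly only on the full 24 rows (r = 0.842/0.608/0.710 and
p = 2.48e−7/1.6e−3/1.0e−4 against printed 0.84/0.61/0.71 and
2.5e−7/0.0016/1.0e−4), so the correlation block defaults to no exclusion.
Both subsets, plus a session-level mode (n = 23), are selectable. The
printed r = 0.37 for channel-10 centroid frequency is not derivable from
the printed feature table under any of these variants (all give ≈ 0.51);
its printed p = 0.076 is internally consistent with r = 0.37 at n = 24,
suggesting it was computed on data not shown in the table. It is reported
for comparison and deliberately not "reproduced".

## Braking model

The three-stroke decomposition assumes constant speed through reaction and
reversing and maximum deceleration thereafter — the conservative
simplification (it over-predicts distance, hence is the safe planning
standard). Water resistance is taken linear in speed, `force = R·V`, which
makes every term of the integrand denominator `RV + P` a power when
multiplied by V; R's functional form is an interpretation (the governing
load code computation is out of scope and R is a user input). The braking
integral is evaluated as `(m u³/P)·g(x)`, `x = Ru/P`,
`g(x) = (x²/2 − x + log1p(x))/x³`, with a series expansion for `x < 10⁻³`
where the direct expression suffers catastrophic cancellation; this single
formula covers R = 0 exactly (`g(0) = 1/3`). Agreement with adaptive
quadrature is better than 10⁻⁸ relative over a 500-point logarithmic sweep
of (u, m, R, P).

The fatigue → reaction-time map `t1 = min(t_base + slope·fss, t_max)`
(defaults 1 s, 0.5 s per fatigue point, 10 s cap) encodes only the
direction supported by the human-factors literature — fatigue lengthens
reaction time — because no functional form or slope is established; it is
a configuration input, not an estimate. Total distance is then monotone
non-decreasing in the fatigue score by construction.

## Problem sizes and numerical tolerances

Generator defaults keep the study's acquisition values (14 channels,
128 Hz, 60 s sessions, 12 subjects × 5 sessions, 40 Stroop trials).
Ensemble tests use scaled-down recordings (8–16 s, 2–10 channels, 20–50
seeds) — sufficient for the Monte-Carlo margins asserted, since Welch CF
estimates at 8 s already resolve the simulated level-0→4 shift of ≈1.5 Hz.
Hand-computed feature examples are asserted to 10⁻¹²; the analytic ridge
solve matches a least-squares oracle at α = 0 to 10⁻¹⁰ relative; filter
attenuation tests compare against the designed transfer function rather
than fixed magic numbers. Degenerate inputs (constant channels, all-zero
spectra, constant correlation inputs, rank-deficient designs at α = 0,
k > n folds) raise informative errors rather than producing NaNs.

## Known limitations

- The synthetic EEG is a spectral-shape model only; conclusions about real
  recordings require real recordings.
- The fatigue model is fit on 22 sessions from 12 subjects; the CV error
  estimate inherits that smallness, and subject identity is not respected
  by the fold split (the study's own procedure appears to be a plain row
  split).
- The printed intercept and one printed correlation cannot be reproduced
  from the printed tables (see above); they are displayed, not asserted.
- EDF input is supported read-only and only when `mne` is installed.
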