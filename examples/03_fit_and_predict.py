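"""Fit the ridge fatigue model on the study tables and score new sessions.

Fits FSS ~ (CF_ch7, PSE_ch7, PSE_ch10) by the analytic ridge solve at
alpha = 0.1 on the 22 model-construction rows, then predicts the fatigue
score for a fresh feature vector. Coefficients are reported on the raw
feature scale (FSS points per Hz / per entropy unit).
"""

from fatiguebrake import apply_exclusions, design_matrix, ridge_fit, study_frame

dm = design_matrix(apply_exclusions(study_frame(), "subject"))
model = ridge_fit(dm, alpha=0.1, standardize=False, loss="mean")

print("fitted coefficients (raw scale):")
for name, b in zip(model.feature_names, model.coefficients_raw):
    print(f"  {name:9s} {b:+.3f}")
print(f"  intercept {model.beta0:+.3f}")

fresh = [[7.5, 0.85, 0.80]]  # CF_ch7 (Hz), PSE_ch7, PSE_ch10
print(f"\npredicted fatigue score for CF_ch7=7.5, PSE_ch7=0.85, PSE_ch10=0.80: "
      f"{model.predict(fresh)[0]:.2f} (0 = none ... 4 = extreme)")
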