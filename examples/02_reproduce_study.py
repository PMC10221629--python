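"""Recompute the study's printed statistics from the packaged tables.

The package ships the printed session summaries of a 12-participant Stroop
fatigue study (reaction times, fatigue scores, channel-7/10 spectral
features). This script reruns the whole analysis - feature-fatigue
correlations, the analytic ridge fit at alpha = 0.1, five-fold
cross-validation and the predicted-vs-actual correlation - and prints each
quantity next to the study's printed value.
"""

from fatiguebrake import reproduce_study
from fatiguebrake.fixtures import report_text

report = reproduce_study(exclusion="subject", metric="mae", n_cv_seeds=100, seed=0)
print(report_text(report))
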