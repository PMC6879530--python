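"""Calibrate the detection threshold τ by asynchronous cross-validation.

A detection requires two consecutive windows with posterior above τ.
2 × 5-fold cross-validation on the calibration trials scores every τ in
{0, 0.025, …, 1}: per fold, held-out trials are scanned and judged at the
trial level (TP = error trial with no pre-onset detection and one within
1.5 s after onset; TN = correct trial with no detection at all).  The
smoothed TPR·TNR product picks τ*.
"""

from errpscan import (
    NoiseModel, make_errp_template, make_session_plan, synthesize_session,
    preprocess_recording, resolve_onsets, crossvalidate_thresholds,
)

plan = make_session_plan(block_count=4, calibration_blocks=4, rng_seed=4)
recording = synthesize_session(plan, make_errp_template(), NoiseModel(), rng_seed=4)
cleaned, _ = preprocess_recording(recording)
trials = resolve_onsets(cleaned.markers, "calibration")

curve = crossvalidate_thresholds(cleaned, trials, rng_seed=4)
print("tau      TPR    TNR    smoothed product")
for i in range(0, 41, 5):
    prod = curve.tpr_smoothed[i] * curve.tnr_smoothed[i]
    mark = "  <-- selected" if curve.tau_grid[i] == curve.selected_tau else ""
    print(f"{curve.tau_grid[i]:.3f}  {curve.tpr[i]:.3f}  {curve.tnr[i]:.3f}  {prod:.3f}{mark}")
print(f"\nselected tau* = {curve.selected_tau:.3f} "
      f"(argmax of smoothed TPR x TNR over the 41-point grid)")
print(f"at tau*: cross-validated TPR = {curve.tpr[curve.tau_grid == curve.selected_tau][0]:.3f}, "
      f"TNR = {curve.tnr[curve.tau_grid == curve.selected_tau][0]:.3f}")
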