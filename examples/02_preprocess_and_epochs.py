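"""Causal preprocessing and epoch extraction.

Removes ocular artifacts by regression on the pre-experiment eye segment,
applies the causal 1–10 Hz Butterworth filter, resolves trial onsets
(ground-truth error onsets for calibration, virtual onsets for correct
trials) and cuts [−0.5, 1.0] s epochs.  Prints the measured ErrP peaks of
the average error epoch at FCz — on causally filtered data the
negativity–positivity–negativity complex appears at ≈0.25/0.35/0.57 s.
"""

from errpscan import (
    NoiseModel, make_errp_template, make_session_plan, synthesize_session,
    preprocess_recording, resolve_onsets, extract_epochs,
)
from errpscan.stats import find_peaks

plan = make_session_plan(block_count=4, calibration_blocks=4, rng_seed=2)
template = make_errp_template()
recording = synthesize_session(plan, template, NoiseModel(), rng_seed=2)

cleaned, eog_model = preprocess_recording(recording)
print(f"EOG model fitted on {eog_model.fitted_on}; "
      f"max |coefficient| = {abs(eog_model.coefficients).max():.2f}")

trials = resolve_onsets(cleaned.markers, "calibration")
epochs = extract_epochs(cleaned, trials)
print(f"epochs: {epochs.epochs.shape[0]} trials × {epochs.epochs.shape[1]} channels × "
      f"{epochs.epochs.shape[2]} samples ([-0.5, 1.0) s at 500 Hz)")

wave = epochs.class_mean("error", "FCz")
peaks = find_peaks(
    epochs.times, wave, [(0.15, 0.30, "neg"), (0.28, 0.45, "pos"), (0.45, 1.0, "neg")]
)
for (lat, amp), name in zip(peaks, ["early negativity", "positivity", "late negativity"]):
    print(f"  {name:17s}: {amp:+6.2f} uV at {lat:.3f} s")
print("(the injected template targets -0.71 / +8.46 / -6.98 uV; residual noise "
      f"of the {int((epochs.class_labels == 'error').sum())}-trial average explains the rest)")
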