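"""Run a small multi-participant study end to end.

Each simulated participant is an independent (template jitter, noise
seed) pair.  Per participant: synthesise a session, preprocess, train on
the calibration blocks, select τ by cross-validation, evaluate the online
blocks with the relaxed online TP rule.  At full scale (15 participants,
12 blocks) this reproduces the benchmark the acceptance script runs; here
3 participants and 4 blocks keep the run short.
"""

import numpy as np

from errpscan import RunConfig, run_study

config = RunConfig(seed=7, participant_count=3, block_count=4, calibration_blocks=3)
study = run_study(config)

print(study.per_participant.to_string(index=False))
print(f"\naverage online TPR = {100 * study.average_tpr:.1f} %, "
      f"TNR = {100 * study.average_tnr:.1f} %")
times = np.concatenate([np.array(v) for v in study.detection_times.values()])
if len(times):
    frac = ((times > 0) & (times <= 1)).mean()
    print(f"{len(times)} ErrP detections in online error trials; "
          f"{100 * frac:.0f} % fall within 1 s of the error onset")
print("(TPR = error trials with a detection after, and none before, the onset; "
      "TNR = correct trials with no detection at all)")
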