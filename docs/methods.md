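# Methods

## The decoding problem

An error-related potential (ErrP) is a stereotyped EEG deflection evoked
when a person perceives an error — here, a robotic arm under the user's
continuous control halting and lifting at an unpredictable moment.
Detecting ErrPs *asynchronously* means scoring the continuous signal at
every sliding-window position without knowing when (or whether) an error
occurred, in contrast to cued, time-locked classification.  The package
implements the full experimental pipeline at desk scale: paradigm-faithful
synthetic sessions, causal preprocessing, a single-window classifier, the
two-consecutive-windows detection rule, per-session threshold calibration,
and trial-level evaluation.

## Paradigm model

A session is 12 blocks of 30 trials.  Per block, 21 trials are *correct*
(the robot reaches the target, duration modelled as Normal(2.02, 0.14) s
truncated to [1.6, 2.5] s) and 9 are *error* trials (control halted,
fixed 6 s duration).  Error positions are drawn uniformly and redrawn
until no more than 2 error trials are consecutive; targets are a balanced
left/right shuffle redrawn until no more than 3 consecutive trials share
a target — the same rejection-sampling scheme the paradigm prescribes.
The first 8 blocks are *calibration*, the last 4 *online*.

Error timing: the paradigm triggers the error when the robot crosses a
distance d_e ~ U[6, 15] cm (≈25–65 % of the path).  Robot kinematics are
not modelled, so the error-marker offset is drawn uniformly on
[0.5, 1.3] s after trial start — the time window corresponding to that
distance range at the mean movement speed.  This preserves the property
the virtual onset relies on: an error can occur at any moment after the
movement begins.  The ground-truth *error onset* (the robot visibly
lifting) follows the marker by a mechanical delay ~ Normal(0.210, 0.004) s
truncated positive.

Three onset definitions drive epoching and evaluation:

| onset             | trials                  | definition                      |
|-------------------|-------------------------|---------------------------------|
| error onset       | calibration error trials| per-trial ground truth          |
| average error onset | online error trials   | marker time + 0.210 s           |
| virtual onset     | correct trials          | trial start + 1 s               |

## Synthetic signals

**ErrP template.** The target waveform at the frontocentral channel (FCz)
is a sum of Gaussian lobes fixed-point-adjusted to attain the reference
peaks — −0.71 μV at 0.246 s, +8.46 μV at 0.354 s, −6.98 μV at 0.568 s —
within ±2 ms / ±0.05 μV.  Those peak values were measured on *causally
filtered* data, so the injected waveform is pre-compensated: it is
expanded on a fixed basis of Gaussian lobes (latencies 0.04–0.92 s every
20 ms, σ = 30 ms) whose filtered responses are linear in the amplitudes;
the amplitudes solve a ridge least-squares fit to the template shape
under equality constraints pinning the filtered value and slope at every
peak.  A causal band-pass rings: the undershoot after the large
positivity can dip below the late-negativity target, so an active-set
loop pins any such rogue extremum to 90 % of the peak value and
re-solves.  The filtered injection then reproduces every printed peak as
the *windowed* extremum of its search region (verified across jittered
templates).

**Scalp topography.** The montage is a 61-channel 10-10 layout (idealised
positions from MNE's standard montage).  The template scales across
channels with a Gaussian of σ = 0.06 m centred at FCz — a stand-in, since
the reference topography exists only as topoplots, not numbers.

**Noise and artifacts** (invented plumbing; the study reports no noise
model): per-channel 1/f background at 5 μV RMS (spectrum flattened below
0.1 Hz), mildly spatially correlated via a Gaussian mixing kernel
(σ = 0.04 m over electrode distance, rows L2-normalised, per-channel RMS
re-normalised exactly).  Three EOG channels carry stereotyped blinks
(raised-cosine, ~150 μV, 8/min during the task) plus 1/f sensor noise;
blinks propagate into the EEG through a frontally decaying mixing matrix.
A 60 s pre-experiment eye-movement segment (elevated blink rate plus
saccades) opens every recording, mirroring the eye runs used to fit the
artifact model, and absorbs the causal filter's warm-up transient.

**Simulated participants.** A participant is a (template jitter, noise
seed) pair: peak amplitudes scaled by ±15 % and latencies shifted by a
common ±20 ms (both uniform), enabling across-participant grand averages
and statistics.

## Preprocessing

Ocular artifacts are removed by *subspace subtraction*, implemented as
its standard reduction: multichannel least-squares regression of EEG on
the three EOG channels with mean removal, fitted once on the eye segment
and applied to the whole recording.  The signal is then band-passed
1–10 Hz with a causal (forward-only) Butterworth filter of order 4, on
the continuous recording, never per epoch — matching what an online
system sees.  Causal filtering shifts apparent component latencies; all
peak values in this package refer to causally filtered data.  Epochs are
cut on the half-open sample interval [onset − 0.5 s, onset + 1.0 s) with
round-to-nearest-sample onset snapping (750 samples at 500 Hz).

## Classifier

Features of a trial are the amplitudes of all channels at every sample of
a 450 ms window starting 300 ms after the onset: 61 × 225 = 13 725
features.  PCA (centred, both classes pooled) keeps the smallest number
of components whose cumulative explained variance reaches 99 % — around
150 of 191 possible on the default benchmark, bracketing the ≈139
reported on the real recordings.  A two-class LDA with the pooled
covariance shrunk toward a scaled identity,
Σ̂ = (1−γ)Σ + γ·(tr Σ/k)·I, scores the reduced features; γ follows the
Ledoit–Wolf rule by default (config override available).  Class priors
are empirical (≈70/30); the threshold calibration below absorbs any prior
choice.

**Posterior calibration.** With 13 725 features estimated from 240
trials, the raw shared-covariance posterior σ(wᵀz + b) is massively
over-confident: noise windows receive posteriors of 10⁻⁶ or 0.9999, and
the entire useful operating range of the threshold grid collapses into
(0.975, 1).  The score is therefore Platt-scaled — p = σ(A·s + B) with
(A, B) fitted by logistic regression on 5-fold out-of-fold scores of the
training data.  The map is monotone, so it changes no decision ranking;
it only restores probability scale, letting the fixed 41-point τ grid
resolve the TPR/TNR trade-off.  `calibration=None` recovers the bare LDA
posterior.

## Asynchronous detection and threshold calibration

The trained window slides over the continuous cleaned signal with an
18 ms leap; each window is stamped at its end (the only causally
available time).  An *ErrP detection* fires whenever two consecutive
windows both exceed τ (strict inequality; a run of n super-threshold
windows yields n−1 detections; a one-per-run mode is available).

Trial-level outcomes: a correct trial is TN iff no detection occurs over
its whole duration.  An error trial is TP iff no detection precedes the
onset and at least one follows it — within 1.5 s in the
calibration/cross-validation definition, at any time up to trial end in
the relaxed online definition (accommodating secondary error responses).

τ is calibrated per session by a 2 × 5-fold asynchronous
cross-validation on the calibration trials: folds are trial-level and
class-stratified (preserving the 70/30 ratio); per fold the PCA + LDA
stack is refit, held-out trials are scanned, and TPR/TNR are computed at
each of the 41 thresholds (0 to 1 in steps of 0.025).  Curves are
averaged over the 10 fold-results, smoothed with a centred 7-sample
moving average (shrunken symmetric windows at the ends), and τ*
maximises the smoothed TPR·TNR product with ties broken toward the
largest τ.  An all-zero product returns the largest τ and flags the
session.

The online evaluation is open-loop: the synthetic signal after a
detection is unchanged.  Under the trial-level definitions above, TP/TN
status never depends on post-detection signal content, so closed-loop
generation would not change any reported rate.

## Electrophysiological summaries

Grand averages are two-level (per-participant mean, then across
participants) with t-based 95 % confidence intervals on the
across-participant means.  Peaks are signed extrema within search
intervals at sample resolution.  Pointwise class differences use
two-sample Wilcoxon rank-sum tests at every epoch sample, Bonferroni
corrected over the 750 samples (α = 0.01), with maximal significant runs
reported as intervals.  The observations entering the rank-sum tests are
per-participant means by default (a grand-average comparison); a
per-trial mode exists, and neither is claimed to be the reference
study's (unstated there).

## Benchmark behaviour and known limitations

On the default benchmark (15 simulated participants, seed 1) the
pipeline averages **TPR ≈ 78 %** and **TNR ≈ 82 %** on the online
blocks, with per-participant τ* mostly 0.82–0.90 and ≈150 retained PCA
components.  Two observations frame these numbers:

* The synthetic conditions set a single-window matched-filter
  discriminability of d′ ≈ 3.  An oracle detector built from the true
  template direction reaches roughly (TPR 0.78, TNR 0.95); the distance
  to it is the estimation noise of a discriminant fit from 240 trials.
  Operating points with TNR ≥ 0.87 at TPR ≥ 0.70 exist on the trained
  detector's ROC, but the product-maximising τ rule deliberately selects
  a more balanced point.
* Detections are emitted along the whole super-threshold run (all-pairs
  rule), and the causally filtered template response spans roughly
  0.6–1.25 s after the onset given the 0.3–0.75 s training window, so
  the detection-time cluster straddles the 1 s mark; its median sits
  near 0.77 s.

What passing tests on this generator do and do not show: the synthetic
background is Gaussian, stationary 1/f noise with a fixed smooth
topography and exactly repeating single-trial ErrPs (up to per-participant
jitter).  Real EEG has rhythmic (alpha), non-stationary and non-Gaussian
structure, trial-to-trial ErrP variability, and artifacts beyond ocular
ones.  Results here validate the *pipeline machinery* — timing
conventions, evaluation rules, calibration logic, statistical summaries —
not claims about real-data performance.

Numerical conventions: half-open sample intervals everywhere; onset
snapping round-to-nearest; 450 ms at 500 Hz = 225 samples; probabilities
clipped to [10⁻¹², 1] so a τ = 0 threshold always fires and τ = 1 never
does; recordings stored as float32 (bit-exact container round-trips);
all randomness flows from explicit seeds (identical seeds give
bit-identical recordings, threshold curves and reports).

Problem sizes: the default study (15 participants × 12 blocks, ~29 min
of 61-channel signal each) runs in roughly 10 minutes on one CPU; unit
tests exercise the same code paths on 8-channel, 1–2-block sessions.
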