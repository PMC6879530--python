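"""Asynchronous sliding-window ErrP detection and threshold calibration.

A trained single-window classifier is slid over the continuous (cleaned,
causally filtered) signal with a leap of 18 ms; every window is stamped
at its *end* time — the only causally available timestamp.  An *ErrP
detection* occurs whenever two consecutive windows both have an
error-class posterior above the threshold τ; a run of n super-threshold
windows therefore yields n−1 detections.

Trial-level evaluation follows the study's definitions:

* TN trial — a correct trial with zero detections over the whole trial;
* TP trial (calibration / cross-validation) — an error trial with no
  detection before the error onset and at least one detection within
  1.5 s after it;
* TP trial (online) — as above but any post-onset detection counts, a
  deliberate relaxation accommodating secondary error potentials.

τ is chosen per session by a 2 × 5-fold asynchronous cross-validation on
the calibration trials: TPR(τ) and TNR(τ) over a 41-point grid are
averaged over folds, smoothed with a 7-sample moving average, and τ*
maximises their product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from errpscan.classifier import (
    PROBABILITY_FLOOR,
    TrainedDetector,
    WindowSpec,
    extract_training_features,
    fit_pca,
    fit_slda,
    project,
)
from errpscan.preprocess import EpochSet, EventConfig, extract_epochs
from errpscan.simulate import ContinuousRecording

DEFAULT_TAU_GRID = np.round(np.arange(41) * 0.025, 6)
CALIBRATION_TP_WINDOW = 1.5   # s after onset in which a detection counts (CV mode)


@dataclass
class DetectorConfig:
    """Everything the asynchronous pipeline needs beyond the data."""

    window: WindowSpec = field(default_factory=WindowSpec)
    variance_threshold: float = 0.99
    shrinkage: str | float = "auto"
    calibration: str | None = "cv"       # Platt-scale the LDA posterior
    leap: float = 0.018                  # s between consecutive window ends
    tau_grid: np.ndarray = field(default_factory=lambda: DEFAULT_TAU_GRID.copy())
    smoothing_window: int = 7
    repetitions: int = 2
    folds: int = 5
    detection_mode: str = "all_pairs"    # or "one_per_run"


@dataclass
class ProbabilityTrace:
    window_end_times: np.ndarray
    probabilities: np.ndarray
    trial_index: int = -1


@dataclass
class Detection:
    time: float
    trial_index: int = -1


@dataclass
class TrialEvaluation:
    trial_index: int
    trial_class: str
    outcome: str                        # TP | TN | FP_trial | FN_trial
    detections: list[Detection]


@dataclass
class ThresholdCurve:
    tau_grid: np.ndarray
    tpr: np.ndarray
    tnr: np.ndarray
    tpr_smoothed: np.ndarray
    tnr_smoothed: np.ndarray
    selected_tau: float
    flagged: bool = False               # True if the TPR·TNR product was all zero


@dataclass
class EvaluationReport:
    trials: list[TrialEvaluation]
    tpr: float
    tnr: float
    detection_times_relative_to_onset: np.ndarray
    mode: str                           # "calibration_cv" | "online"
    tau: float


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def scan(
    eeg: np.ndarray,
    sample_rate: float,
    detector: TrainedDetector,
    start_time: float,
    stop_time: float,
    leap: float = 0.018,
    trial_index: int = -1,
) -> ProbabilityTrace:
    """Score sliding windows over [start_time, stop_time] of a continuous signal.

    Windows have the detector's training length, the first one ends at
    ``start_time + window.length``, and successive windows step by
    ``leap`` (which must be a positive multiple of the sample period).
    Returns an empty trace if the segment is shorter than one window.
    """
    leap_samples = int(round(leap * sample_rate))
    if leap_samples <= 0 or abs(leap * sample_rate - leap_samples) > 1e-6:
        raise ValueError(f"leap {leap} s is not a positive multiple of the sample period")
    w = detector.window.n_samples(sample_rate)
    i0 = int(round(start_time * sample_rate))
    i1 = int(round(stop_time * sample_rate))
    if i0 < 0 or i1 > eeg.shape[1]:
        raise ValueError("scan interval not covered by the signal")
    seg_len = i1 - i0
    if seg_len < w:
        return ProbabilityTrace(np.empty(0), np.empty(0), trial_index)
    n_win = (seg_len - w) // leap_samples + 1
    v, c = detector.linear_functional()
    views = sliding_window_view(eeg[:, i0:i1], w, axis=1)[:, ::leap_samples][:, :n_win]
    scores = np.einsum("cnw,cw->n", np.asarray(views, dtype=float), v) + c
    probs = np.clip(expit(scores), PROBABILITY_FLOOR, 1.0)
    times = start_time + (w + np.arange(n_win) * leap_samples) / sample_rate
    return ProbabilityTrace(window_end_times=times, probabilities=probs, trial_index=trial_index)


def detect(trace: ProbabilityTrace, tau: float, mode: str = "all_pairs") -> list[Detection]:
    """Detections at every window whose probability and its predecessor's exceed τ.

    ``mode="one_per_run"`` keeps only the first detection of each
    super-threshold run.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    p = trace.probabilities
    if len(p) < 2:
        return []
    above = p > tau
    pair = above[1:] & above[:-1]
    if mode == "one_per_run":
        pair = pair & ~np.concatenate(([False], pair[:-1]))
    elif mode != "all_pairs":
        raise ValueError(f"unknown detection mode {mode!r}")
    times = trace.window_end_times[1:][pair]
    return [Detection(time=float(t), trial_index=trace.trial_index) for t in times]


# ---------------------------------------------------------------------------
# Trial evaluation
# ---------------------------------------------------------------------------

def evaluate_trial(
    detections: list[Detection],
    trial_start: float,
    trial_end: float,
    onset: float,
    trial_class: str,
    mode: str,
    trial_index: int = -1,
) -> TrialEvaluation:
    """Classify one trial's detections as TP/TN/FP_trial/FN_trial.

    ``detections`` must already be restricted to [trial_start, trial_end].
    """
    if mode not in ("calibration", "online"):
        raise ValueError(f"mode must be 'calibration' or 'online', got {mode!r}")
    if not trial_start <= onset <= trial_end:
        raise ValueError(f"onset {onset} outside trial bounds [{trial_start}, {trial_end}]")
    times = np.array([d.time for d in detections])
    if trial_class == "correct":
        outcome = "TN" if len(times) == 0 else "FP_trial"
    else:
        pre = np.any(times < onset) if len(times) else False
        if mode == "calibration":
            post = np.any((times > onset) & (times <= onset + CALIBRATION_TP_WINDOW)) if len(times) else False
        else:
            post = np.any(times > onset) if len(times) else False
        outcome = "TP" if (not pre and post) else "FN_trial"
    return TrialEvaluation(
        trial_index=trial_index, trial_class=trial_class, outcome=outcome, detections=detections
    )


def _success_over_grid(
    trace: ProbabilityTrace,
    onset: float,
    trial_class: str,
    tau_grid: np.ndarray,
    mode: str,
) -> np.ndarray:
    """Vectorised TN/TP indicator per τ for one trial.

    Equivalent to running :func:`detect` + :func:`evaluate_trial` at every
    grid point: a detection pair exists above τ iff min(pᵢ, pᵢ₋₁) > τ, so
    region-wise maxima of the pair minima decide every τ at once.
    """
    p = trace.probabilities
    if len(p) < 2:
        # no detection possible at any τ
        return (np.ones_like(tau_grid, dtype=bool) if trial_class == "correct"
                else np.zeros_like(tau_grid, dtype=bool))
    pair_min = np.minimum(p[1:], p[:-1])
    t = trace.window_end_times[1:]
    if trial_class == "correct":
        return pair_min.max() <= tau_grid
    pre = pair_min[t < onset]
    if mode == "calibration":
        post = pair_min[(t > onset) & (t <= onset + CALIBRATION_TP_WINDOW)]
    else:
        post = pair_min[t > onset]
    pre_max = pre.max() if len(pre) else -np.inf
    post_max = post.max() if len(post) else -np.inf
    return (pre_max <= tau_grid) & (post_max > tau_grid)


# ---------------------------------------------------------------------------
# Threshold calibration (asynchronous cross-validation)
# ---------------------------------------------------------------------------

def smooth_curve(values: np.ndarray, window: int = 7) -> np.ndarray:
    """Centred moving average; the ends use the available symmetric window."""
    if window % 2 == 0 or window < 1:
        raise ValueError("smoothing window must be odd and positive")
    values = np.asarray(values, dtype=float)
    n = len(values)
    if window > n:
        raise ValueError("smoothing window exceeds curve length")
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        h = min(i, n - 1 - i, half)
        out[i] = values[i - h : i + h + 1].mean()
    return out


def select_threshold(curve: ThresholdCurve) -> float:
    """τ* maximising smoothed TPR × smoothed TNR; ties break to the largest τ."""
    product = curve.tpr_smoothed * curve.tnr_smoothed
    if np.all(product == 0):
        curve.selected_tau = float(curve.tau_grid[-1])
        curve.flagged = True
        return curve.selected_tau
    best = product.max()
    idx = int(np.flatnonzero(product == best)[-1])
    curve.selected_tau = float(curve.tau_grid[idx])
    curve.flagged = False
    return curve.selected_tau


def _scan_trials(
    recording: ContinuousRecording,
    trials: pd.DataFrame,
    detector: TrainedDetector,
    leap: float,
) -> list[ProbabilityTrace]:
    return [
        scan(
            recording.eeg, recording.sample_rate, detector,
            float(row["start_s"]), float(row["end_s"]), leap,
            trial_index=int(row["trial_index"]),
        )
        for _, row in trials.iterrows()
    ]


def crossvalidate_thresholds(
    recording: ContinuousRecording,
    trials: pd.DataFrame,
    config: DetectorConfig | None = None,
    event_config: EventConfig | None = None,
    rng_seed: int = 0,
    epochs: EpochSet | None = None,
) -> ThresholdCurve:
    """2 × 5-fold asynchronous cross-validation of the τ grid.

    ``trials`` is the calibration trial table from
    :func:`errpscan.preprocess.resolve_onsets` (calibration mode).  Folds
    are trial-level and class-stratified.  Per fold the PCA + LDA stack
    is refit on the training trials' single-window features, every
    held-out trial is scanned asynchronously, and fold TPR/TNR are
    computed at every τ with the calibration-mode trial rules; curves are
    averaged over repetitions × folds, smoothed, and τ* selected.
    """
    config = config or DetectorConfig()
    event_config = event_config or EventConfig()
    tau_grid = np.asarray(config.tau_grid, dtype=float)

    if epochs is None:
        epochs = extract_epochs(recording, trials, event_config)
    x, labels = extract_training_features(epochs, config.window)
    y = labels == "error"
    n_per_class = min(int(np.sum(y)), int(np.sum(~y)))
    if n_per_class < config.folds:
        raise ValueError(
            f"need at least {config.folds} trials per class for stratified "
            f"{config.folds}-fold CV, got {n_per_class}"
        )

    trials = trials.reset_index(drop=True)
    tpr_folds: list[np.ndarray] = []
    tnr_folds: list[np.ndarray] = []
    for rep in range(config.repetitions):
        skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=(rng_seed + rep) % (2**31))
        for train_idx, test_idx in skf.split(x, y):
            if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
                raise ValueError("a cross-validation fold is missing a class")
            pca = fit_pca(x[train_idx], config.variance_threshold)
            lda = fit_slda(
                project(pca, x[train_idx]), y[train_idx], config.shrinkage, config.calibration
            )
            det = TrainedDetector(
                pca=pca, lda=lda, window=config.window,
                sample_rate=epochs.sample_rate, channel_count=epochs.epochs.shape[1],
            )
            tp = np.zeros_like(tau_grid)
            tn = np.zeros_like(tau_grid)
            n_err = n_cor = 0
            for k in test_idx:
                row = trials.iloc[k]
                trace = scan(
                    recording.eeg, recording.sample_rate, det,
                    float(row["start_s"]), float(row["end_s"]), config.leap,
                    trial_index=int(row["trial_index"]),
                )
                ok = _success_over_grid(
                    trace, float(row["onset_s"]), str(row["trial_class"]), tau_grid, "calibration"
                )
                if row["trial_class"] == "error":
                    tp += ok
                    n_err += 1
                else:
                    tn += ok
                    n_cor += 1
            tpr_folds.append(tp / n_err)
            tnr_folds.append(tn / n_cor)

    tpr = np.mean(tpr_folds, axis=0)
    tnr = np.mean(tnr_folds, axis=0)
    curve = ThresholdCurve(
        tau_grid=tau_grid,
        tpr=tpr,
        tnr=tnr,
        tpr_smoothed=smooth_curve(tpr, config.smoothing_window),
        tnr_smoothed=smooth_curve(tnr, config.smoothing_window),
        selected_tau=float("nan"),
    )
    select_threshold(curve)
    return curve


# ---------------------------------------------------------------------------
# Online evaluation
# ---------------------------------------------------------------------------

def detections_to_frame(report: "EvaluationReport", trials: pd.DataFrame) -> pd.DataFrame:
    """Flatten a report's detections to rows of (trial_index, time_s, time_rel_onset_s)."""
    onsets = trials.set_index("trial_index")["onset_s"]
    rows = [
        (ev.trial_index, d.time, d.time - float(onsets[ev.trial_index]))
        for ev in report.trials
        for d in ev.detections
    ]
    return pd.DataFrame(rows, columns=["trial_index", "time_s", "time_rel_onset_s"])


def run_online_evaluation(
    detector: TrainedDetector,
    tau: float,
    recording: ContinuousRecording,
    trials: pd.DataFrame,
    config: DetectorConfig | None = None,
    mode: str = "online",
) -> EvaluationReport:
    """Scan and evaluate a block of trials at a fixed threshold.

    ``trials`` is the trial table from ``resolve_onsets`` for the online
    blocks (average error onsets).  Detection times of error trials are
    reported relative to the onset, for the detection-latency summary.
    """
    config = config or DetectorConfig()
    if len(trials) == 0:
        raise ValueError("no trials to evaluate")
    evaluations = []
    rel_times = []
    n_tp = n_err = n_tn = n_cor = 0
    for _, row in trials.iterrows():
        trace = scan(
            recording.eeg, recording.sample_rate, detector,
            float(row["start_s"]), float(row["end_s"]), config.leap,
            trial_index=int(row["trial_index"]),
        )
        detections = detect(trace, tau, config.detection_mode)
        ev = evaluate_trial(
            detections, float(row["start_s"]), float(row["end_s"]), float(row["onset_s"]),
            str(row["trial_class"]), mode, trial_index=int(row["trial_index"]),
        )
        evaluations.append(ev)
        if ev.trial_class == "error":
            n_err += 1
            n_tp += ev.outcome == "TP"
            rel_times.extend(d.time - float(row["onset_s"]) for d in detections)
        else:
            n_cor += 1
            n_tn += ev.outcome == "TN"
    return EvaluationReport(
        trials=evaluations,
        tpr=n_tp / n_err if n_err else float("nan"),
        tnr=n_tn / n_cor if n_cor else float("nan"),
        detection_times_relative_to_onset=np.array(rel_times),
        mode=mode if mode == "online" else "calibration_cv",
        tau=float(tau),
    )
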