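"""End-to-end desk-scale study: simulate → preprocess → calibrate → evaluate.

For each simulated participant (a jittered ErrP template plus an
independent noise realisation) the runner

1. synthesises a 12-block session (8 calibration + 4 online blocks),
2. removes EOG artifacts and applies the causal 1–10 Hz band-pass,
3. trains the PCA(99 %) + shrinkage-LDA classifier on the calibration
   epochs and selects τ by 2 × 5-fold asynchronous cross-validation
   (maximum of smoothed TPR × TNR over the 41-point grid),
4. evaluates the online blocks with the relaxed online TP definition,

and aggregates per-participant TPR/TNR/τ, detection latencies and the
grand-average electrophysiology at the frontocentral channel.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from errpscan.classifier import train_detector
from errpscan.detection import (
    DetectorConfig,
    ThresholdCurve,
    crossvalidate_thresholds,
    run_online_evaluation,
)
from errpscan.montage import EEG_CHANNELS, FRONTOCENTRAL
from errpscan.preprocess import (
    EventConfig,
    FilterSpec,
    extract_epochs,
    preprocess_recording,
    resolve_onsets,
)
from errpscan.simulate import (
    DEFAULT_PEAK_SPEC,
    NoiseModel,
    jittered_peak_spec,
    make_errp_template,
    make_session_plan,
    synthesize_session,
)
from errpscan.stats import (
    GrandAverage,
    SignificanceMask,
    find_peaks,
    grand_average,
    pointwise_significance,
    unit_class_means,
)

logger = logging.getLogger("errpscan")

#: Search intervals for the three ErrP components on causally filtered data.
PEAK_SEARCH_INTERVALS = [(0.15, 0.30, "neg"), (0.28, 0.45, "pos"), (0.45, 1.0, "neg")]


@dataclass
class RunConfig:
    """Study configuration; defaults follow the paradigm's printed values."""

    seed: int = 1
    participant_count: int = 15
    block_count: int = 12
    calibration_blocks: int = 8
    n_trials_per_block: int = 30
    error_fraction: float = 0.30
    peak_spec: tuple[tuple[float, float], ...] = DEFAULT_PEAK_SPEC
    spatial_width: float = 0.06
    amplitude_jitter: float = 0.15
    latency_jitter: float = 0.020
    sample_rate: float = 500.0
    channel_labels: tuple[str, ...] = EEG_CHANNELS
    noise: NoiseModel = field(default_factory=NoiseModel)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    event: EventConfig = field(default_factory=EventConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    significance_alpha: float = 0.01

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise"]["eog_mixing"] = (
            None if self.noise.eog_mixing is None else np.asarray(self.noise.eog_mixing).tolist()
        )
        d["detector"]["tau_grid"] = np.asarray(self.detector.tau_grid).tolist()
        return d


@dataclass
class ParticipantResult:
    participant: int
    tpr: float
    tnr: float
    tau: float
    n_components: int
    flagged_tau: bool
    detection_times_relative_to_onset: np.ndarray
    threshold_curve: ThresholdCurve
    calibration_epochs: object = None      # EpochSet at full channel set


@dataclass
class StudyReport:
    per_participant: pd.DataFrame           # participant, tpr, tnr, tau, n_components
    average_tpr: float
    average_tnr: float
    detection_times: dict[int, list[float]]
    grand_avg: GrandAverage | None
    significance: SignificanceMask | None
    error_peaks: list[tuple[float, float]] | None
    config_echo: dict
    threshold_curves: dict[int, ThresholdCurve] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config_echo,
            "per_participant": self.per_participant.to_dict(orient="records"),
            "average_tpr": self.average_tpr,
            "average_tnr": self.average_tnr,
            "detection_times_relative_to_onset": {
                str(k): list(v) for k, v in self.detection_times.items()
            },
            "error_peaks": self.error_peaks,
            "significant_intervals": (
                self.significance.significant_intervals if self.significance else None
            ),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def participant_seeds(seed: int, participant_count: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(participant_count)


def run_participant(
    config: RunConfig,
    seed_seq: np.random.SeedSequence,
    participant: int,
    keep_epochs: bool = True,
) -> ParticipantResult:
    """Simulate and evaluate a single participant end to end."""
    t0 = time.perf_counter()
    rng = np.random.default_rng(seed_seq)
    cv_seed = int(seed_seq.generate_state(2)[1] % (2**31))

    peaks = jittered_peak_spec(
        config.peak_spec, rng, config.amplitude_jitter, config.latency_jitter
    )
    template = make_errp_template(
        peaks,
        spatial_width=config.spatial_width,
        sample_rate=config.sample_rate,
        channel_labels=config.channel_labels,
    )
    plan = make_session_plan(
        block_count=config.block_count,
        calibration_blocks=config.calibration_blocks,
        n_trials=config.n_trials_per_block,
        error_fraction=config.error_fraction,
        rng_seed=rng,
    )
    recording = synthesize_session(
        plan, template, config.noise, rng, filter_spec=config.filter_spec
    )
    cleaned, _eog = preprocess_recording(recording, config.filter_spec)

    n_calib = config.calibration_blocks * config.n_trials_per_block
    calib_trials = resolve_onsets(cleaned.markers, "calibration", config.event)
    calib_trials = calib_trials[calib_trials["trial_index"] < n_calib].reset_index(drop=True)
    online_trials = resolve_onsets(cleaned.markers, "online", config.event)
    online_trials = online_trials[online_trials["trial_index"] >= n_calib].reset_index(drop=True)

    calib_epochs = extract_epochs(cleaned, calib_trials, config.event)
    curve = crossvalidate_thresholds(
        cleaned, calib_trials, config.detector, config.event, cv_seed, epochs=calib_epochs
    )
    detector = train_detector(
        calib_epochs,
        config.detector.window,
        config.detector.variance_threshold,
        config.detector.shrinkage,
        config.detector.calibration,
    )
    report = run_online_evaluation(
        detector, curve.selected_tau, cleaned, online_trials, config.detector
    )
    logger.info(
        "participant %d: tau=%.3f tpr=%.3f tnr=%.3f k=%d (%.1f s)",
        participant, curve.selected_tau, report.tpr, report.tnr,
        detector.pca.n_components, time.perf_counter() - t0,
    )
    return ParticipantResult(
        participant=participant,
        tpr=report.tpr,
        tnr=report.tnr,
        tau=curve.selected_tau,
        n_components=detector.pca.n_components,
        flagged_tau=curve.flagged,
        detection_times_relative_to_onset=report.detection_times_relative_to_onset,
        threshold_curve=curve,
        calibration_epochs=calib_epochs if keep_epochs else None,
    )


def run_study(config: RunConfig) -> StudyReport:
    """Run the full multi-participant study and aggregate the results."""
    seeds = participant_seeds(config.seed, config.participant_count)
    results = [
        run_participant(config, ss, p + 1)
        for p, ss in enumerate(seeds)
    ]
    rows = [
        {
            "participant": r.participant,
            "tpr": r.tpr,
            "tnr": r.tnr,
            "tau": r.tau,
            "n_components": r.n_components,
        }
        for r in results
    ]
    table = pd.DataFrame(rows)

    ga = mask = peaks = None
    epoch_sets = [r.calibration_epochs for r in results if r.calibration_epochs is not None]
    if len(epoch_sets) >= 2:
        channel = FRONTOCENTRAL if FRONTOCENTRAL in epoch_sets[0].channel_labels else epoch_sets[0].channel_labels[0]
        ga = grand_average(epoch_sets, channel)
        peaks = find_peaks(ga.times, ga.mean_error, PEAK_SEARCH_INTERVALS)
        if len(epoch_sets) >= 5:
            correct, error = unit_class_means(epoch_sets, channel)
            mask = pointwise_significance(correct, error, ga.times, config.significance_alpha)

    return StudyReport(
        per_participant=table,
        average_tpr=float(table["tpr"].mean()),
        average_tnr=float(table["tnr"].mean()),
        detection_times={
            r.participant: [float(t) for t in r.detection_times_relative_to_onset]
            for r in results
        },
        grand_avg=ga,
        significance=mask,
        error_peaks=peaks,
        config_echo=config.to_dict(),
        threshold_curves={r.participant: r.threshold_curve for r in results},
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report(study: StudyReport, out_dir: str | Path, formats: tuple[str, ...] = ("json", "csv")) -> list[Path]:
    """Write the study report as JSON/CSV tables (and optional figures)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for fmt in formats:
        if fmt == "json":
            p = out_dir / "study.json"
            p.write_text(study.to_json())
            written.append(p)
        elif fmt == "csv":
            table = study.per_participant.copy()
            avg = {
                "participant": "average",
                "tpr": study.average_tpr,
                "tnr": study.average_tnr,
                "tau": table["tau"].mean(),
                "n_components": table["n_components"].mean(),
            }
            full = pd.concat([table, pd.DataFrame([avg])], ignore_index=True)
            p = out_dir / "per_participant.csv"
            full.to_csv(p, index=False)
            written.append(p)
            rows = [
                {"participant": k, "time_rel_onset_s": t}
                for k, ts in study.detection_times.items()
                for t in ts
            ]
            p = out_dir / "detection_times.csv"
            pd.DataFrame(rows, columns=["participant", "time_rel_onset_s"]).to_csv(p, index=False)
            written.append(p)
            if study.grand_avg is not None:
                ga = study.grand_avg
                df = pd.DataFrame(
                    {
                        "time_s": ga.times,
                        "mean_correct": ga.mean_correct,
                        "mean_error": ga.mean_error,
                        "ci_low_correct": ga.ci_low_correct,
                        "ci_high_correct": ga.ci_high_correct,
                        "ci_low_error": ga.ci_low_error,
                        "ci_high_error": ga.ci_high_error,
                    }
                )
                if study.significance is not None:
                    df["p"] = study.significance.p_values
                    df["significant"] = study.significance.significant
                p = out_dir / "grand_average.csv"
                df.to_csv(p, index=False)
                written.append(p)
        elif fmt == "figures":
            written.extend(_write_figures(study, out_dir))
        else:
            raise ValueError(f"unknown report format {fmt!r}")
    return written


def _write_figures(study: StudyReport, out_dir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    if study.grand_avg is not None:
        ga = study.grand_avg
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(ga.times, ga.mean_correct, color="green", label="correct")
        ax.fill_between(ga.times, ga.ci_low_correct, ga.ci_high_correct, color="green", alpha=0.2)
        ax.plot(ga.times, ga.mean_error, color="red", label="error")
        ax.fill_between(ga.times, ga.ci_low_error, ga.ci_high_error, color="red", alpha=0.2)
        if study.significance is not None:
            for a, b in study.significance.significant_intervals:
                ax.axvspan(a, b, color="grey", alpha=0.3)
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_xlabel("time relative to onset (s)")
        ax.set_ylabel("amplitude (μV)")
        ax.legend()
        p = out_dir / "grand_average.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    fig, ax = plt.subplots(figsize=(8, 4))
    t = study.per_participant
    x = np.arange(len(t))
    ax.bar(x - 0.2, t["tnr"], width=0.4, color="green", label="TNR")
    ax.bar(x + 0.2, t["tpr"], width=0.4, color="red", label="TPR")
    for xi, tau in zip(x, t["tau"]):
        ax.text(xi, 1.02, f"{tau:.2f}", ha="center", fontsize=7, color="blue")
    ax.set_xticks(x, t["participant"])
    ax.set_ylim(0, 1.1)
    ax.set_xlabel("participant")
    ax.legend(loc="lower right")
    p = out_dir / "per_participant.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(p)
    return written
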