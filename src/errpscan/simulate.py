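"""Synthetic sessions for the asynchronous ErrP-decoding paradigm.

The study this package models measured 61-channel EEG (plus 3 EOG
channels) at 500 Hz while participants steered a robotic arm to a target.
Each session had 12 blocks of 30 trials; 30 % of the trials were *error
trials* in which the robot was halted and lifted at an unpredictable
moment (the *error onset*), eliciting an error-related potential (ErrP).
The first 8 blocks were used for classifier calibration, the last 4 for
online evaluation.  The recorded dataset is not public, so this module
generates paradigm-faithful surrogate sessions:

* block plans with the paradigm's run-length constraints (max 2
  consecutive error trials, max 3 consecutive same-target trials),
  produced by the same rejection-sampling procedure;
* an ErrP template whose *causally filtered* average reproduces the
  printed peak amplitudes/latencies at the frontocentral channel;
* spatially correlated 1/f background noise and EOG (blink/saccade)
  artifacts mixed into the EEG.

Error trials carry an ``error_marker`` and, a robot-mechanics delay of
about 0.210 s later, the ground-truth ``error_onset_truth`` at which the
template is injected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.fft
from scipy import stats

from errpscan.montage import (
    EEG_CHANNELS,
    EOG_CHANNELS,
    FRONTOCENTRAL,
    channel_positions,
    gaussian_scalp_pattern,
)

DEFAULT_PEAK_SPEC: tuple[tuple[float, float], ...] = (
    (0.246, -0.71),
    (0.354, 8.46),
    (0.568, -6.98),
)

MARKER_KINDS = ("trial_start", "trial_end", "error_marker", "error_onset_truth", "target_hit")

_MAX_REDRAWS = 1000


# ---------------------------------------------------------------------------
# Session plans
# ---------------------------------------------------------------------------

@dataclass
class TrialSpec:
    """One planned trial: class, target side and timing."""

    trial_class: str                      # "correct" | "error"
    target: str                           # "left" | "right"
    error_distance_de: float | None = None   # cm, error trials only
    planned_duration: float | None = None    # s
    error_onset_offset: float | None = None  # s after trial start, error trials

    @property
    def is_error(self) -> bool:
        return self.trial_class == "error"


@dataclass
class BlockPlan:
    trial_specs: list[TrialSpec]
    block_index: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.trial_specs)

    @property
    def n_error_trials(self) -> int:
        return sum(t.is_error for t in self.trial_specs)


@dataclass
class SessionPlan:
    blocks: list[BlockPlan]
    calibration_block_count: int

    @property
    def online_block_count(self) -> int:
        return len(self.blocks) - self.calibration_block_count

    def iter_trials(self):
        """Yield (global_trial_index, block_index, is_calibration, TrialSpec)."""
        idx = 0
        for b, block in enumerate(self.blocks):
            for spec in block.trial_specs:
                yield idx, b, b < self.calibration_block_count, spec
                idx += 1


def _max_run(values: np.ndarray) -> int:
    """Length of the longest run of identical consecutive entries."""
    if len(values) == 0:
        return 0
    change = np.flatnonzero(np.asarray(values[1:]) != np.asarray(values[:-1]))
    edges = np.concatenate(([-1], change, [len(values) - 1]))
    return int(np.max(np.diff(edges)))


def max_error_run(plan: BlockPlan) -> int:
    best = run = 0
    for spec in plan.trial_specs:
        run = run + 1 if spec.is_error else 0
        best = max(best, run)
    return best


def max_target_run(plan: BlockPlan) -> int:
    return _max_run(np.array([t.target for t in plan.trial_specs]))


def make_block_plan(
    n_trials: int = 30,
    error_fraction: float = 0.30,
    max_consec_errors: int = 2,
    max_consec_same_target: int = 3,
    rng_seed: int | np.random.Generator = 0,
) -> BlockPlan:
    """Draw a block plan by rejection sampling.

    Error-trial positions are placed uniformly and redrawn until no more
    than ``max_consec_errors`` error trials are consecutive; targets are a
    balanced left/right shuffle redrawn until no more than
    ``max_consec_same_target`` consecutive trials share a target.
    """
    if not 0.0 <= error_fraction <= 1.0:
        raise ValueError("error_fraction must be in [0, 1]")
    if n_trials % 2 != 0:
        raise ValueError("n_trials must be even for a balanced target split")
    n_err_f = error_fraction * n_trials
    n_err = int(round(n_err_f))
    if abs(n_err_f - n_err) > 1e-9:
        raise ValueError("error_fraction × n_trials must be an integer")

    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed

    flags = np.zeros(n_trials, dtype=bool)
    if n_err > 0:
        for attempt in range(_MAX_REDRAWS):
            flags[:] = False
            flags[rng.choice(n_trials, size=n_err, replace=False)] = True
            run, best = 0, 0
            for f in flags:
                run = run + 1 if f else 0
                best = max(best, run)
            if best <= max_consec_errors:
                break
        else:
            raise RuntimeError(
                f"could not place {n_err} error trials with max run "
                f"{max_consec_errors} in {_MAX_REDRAWS} redraws"
            )

    targets = np.array(["left"] * (n_trials // 2) + ["right"] * (n_trials // 2))
    for attempt in range(_MAX_REDRAWS):
        rng.shuffle(targets)
        if _max_run(targets) <= max_consec_same_target:
            break
    else:
        raise RuntimeError(
            f"could not draw a balanced target sequence with max run "
            f"{max_consec_same_target} in {_MAX_REDRAWS} redraws"
        )

    specs = []
    for f, tgt in zip(flags, targets):
        de = float(rng.uniform(6.0, 15.0)) if f else None
        specs.append(TrialSpec(trial_class="error" if f else "correct", target=str(tgt), error_distance_de=de))
    return BlockPlan(trial_specs=specs)


def make_session_plan(
    block_count: int = 12,
    calibration_blocks: int = 8,
    n_trials: int = 30,
    error_fraction: float = 0.30,
    max_consec_errors: int = 2,
    max_consec_same_target: int = 3,
    correct_duration_mean: float = 2.02,
    correct_duration_sd: float = 0.14,
    correct_duration_bounds: tuple[float, float] = (1.6, 2.5),
    error_trial_duration: float = 6.0,
    error_onset_interval: tuple[float, float] = (0.5, 1.3),
    rng_seed: int | np.random.Generator = 0,
) -> SessionPlan:
    """Assemble a full session of independent block plans with trial timing.

    Correct-trial durations follow a truncated Normal(2.02, 0.14) s (the
    reported mean ± sd of the time to reach the target); error trials last
    the paradigm's fixed 6 s.  The error-marker offset within an error
    trial is uniform over ``error_onset_interval`` (default [0.5, 1.3] s,
    mirroring errors triggered at 25–65 % of the robot's path).
    """
    if calibration_blocks > block_count:
        raise ValueError("calibration_blocks must be ≤ block_count")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    lo, hi = correct_duration_bounds
    a = (lo - correct_duration_mean) / correct_duration_sd
    b = (hi - correct_duration_mean) / correct_duration_sd
    blocks = []
    for bi in range(block_count):
        plan = make_block_plan(n_trials, error_fraction, max_consec_errors, max_consec_same_target, rng)
        plan.block_index = bi
        for spec in plan.trial_specs:
            if spec.is_error:
                spec.planned_duration = float(error_trial_duration)
                spec.error_onset_offset = float(rng.uniform(*error_onset_interval))
            else:
                spec.planned_duration = float(
                    stats.truncnorm.rvs(a, b, loc=correct_duration_mean, scale=correct_duration_sd, random_state=rng)
                )
        blocks.append(plan)
    return SessionPlan(blocks=blocks, calibration_block_count=calibration_blocks)


# ---------------------------------------------------------------------------
# ErrP template
# ---------------------------------------------------------------------------

@dataclass
class ErrPTemplate:
    """Ground-truth ErrP waveform and its scalp distribution.

    ``waveform`` is the target shape *as it should appear after the
    pipeline's causal band-pass filter*, sampled at ``sample_rate`` on
    [0, 1] s relative to the error onset.  ``lobes`` holds the Gaussian
    lobe parameters (latency s, amplitude μV, sigma s) that generate it.
    """

    waveform: np.ndarray
    spatial_pattern: np.ndarray
    peak_spec: tuple[tuple[float, float], ...]
    lobes: np.ndarray               # (n, 3): latency, amplitude, sigma
    sample_rate: float
    channel_labels: tuple[str, ...]
    spatial_center: str = FRONTOCENTRAL

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.waveform)) / self.sample_rate


def _sum_of_lobes(lobes: np.ndarray, t: np.ndarray) -> np.ndarray:
    w = np.zeros_like(t)
    for lat, amp, sig in lobes:
        w += amp * np.exp(-((t - lat) ** 2) / (2.0 * sig**2))
    return w


def _measure_peaks(
    w: np.ndarray, t: np.ndarray, targets: np.ndarray, half_window: float
) -> tuple[np.ndarray, np.ndarray]:
    """Signed extremum (latency, amplitude) near each target latency."""
    lats = np.empty(len(targets))
    amps = np.empty(len(targets))
    for i, (lat, amp) in enumerate(targets):
        sel = (t >= lat - half_window) & (t <= lat + half_window)
        seg = w[sel]
        idx = int(np.argmax(seg)) if amp >= 0 else int(np.argmin(seg))
        lats[i] = t[sel][idx]
        amps[i] = seg[idx]
    return lats, amps


def make_errp_template(
    peak_spec: tuple[tuple[float, float], ...] | list[tuple[float, float]] = DEFAULT_PEAK_SPEC,
    spatial_center: str = FRONTOCENTRAL,
    spatial_width: float = 0.06,
    sample_rate: float = 500.0,
    lobe_sigma: float = 0.04,
    channel_labels: tuple[str, ...] = EEG_CHANNELS,
) -> ErrPTemplate:
    """Build a smooth ErrP waveform hitting every specified peak.

    The waveform is a sum of Gaussian lobes; lobe amplitudes/latencies are
    fixed-point adjusted so each specified (latency, amplitude) pair is
    attained within ±2 ms / ±0.05 μV despite lobe overlap.  The default
    peaks are the printed grand-average values at the frontocentral
    channel: −0.71 μV @ 0.246 s, +8.46 μV @ 0.354 s, −6.98 μV @ 0.568 s.
    """
    peak_spec = tuple((float(l), float(a)) for l, a in peak_spec)
    spatial = gaussian_scalp_pattern(channel_labels, spatial_center, spatial_width)
    n = int(round(sample_rate * 1.0)) + 1
    t = np.arange(n) / sample_rate

    if len(peak_spec) == 0:
        return ErrPTemplate(
            waveform=np.zeros(n), spatial_pattern=spatial, peak_spec=peak_spec,
            lobes=np.zeros((0, 3)), sample_rate=sample_rate,
            channel_labels=tuple(channel_labels), spatial_center=spatial_center,
        )

    lats = np.array([p[0] for p in peak_spec])
    amps = np.array([p[1] for p in peak_spec])
    if not np.all(np.diff(lats) > 0):
        raise ValueError("peak latencies must be strictly increasing")
    if np.any(lats <= 0) or np.any(lats >= 1.0):
        raise ValueError("peak latencies must lie within (0, 1) s")
    if len(lats) > 1 and np.min(np.diff(lats)) < 0.040:
        raise ValueError("peaks closer than 40 ms are unresolvable at the default lobe width")

    targets = np.array(peak_spec)
    lobes = np.column_stack([lats, amps, np.full(len(lats), lobe_sigma)])
    for _ in range(200):
        w = _sum_of_lobes(lobes, t)
        got_l, got_a = _measure_peaks(w, t, targets, half_window=0.035)
        dl = targets[:, 0] - got_l
        da = targets[:, 1] - got_a
        if np.all(np.abs(dl) < 0.5 / sample_rate) and np.all(np.abs(da) < 0.005):
            break
        lobes[:, 0] += np.where(np.abs(dl) >= 0.5 / sample_rate, dl, 0.0)
        lobes[:, 1] += da
    w = _sum_of_lobes(lobes, t)
    got_l, got_a = _measure_peaks(w, t, targets, half_window=0.035)
    if np.any(np.abs(got_l - targets[:, 0]) > 0.002 + 1e-12) or np.any(
        np.abs(got_a - targets[:, 1]) > 0.05
    ):
        raise RuntimeError("template fixed-point adjustment did not reach the peak tolerance")

    return ErrPTemplate(
        waveform=w, spatial_pattern=spatial, peak_spec=peak_spec, lobes=lobes,
        sample_rate=sample_rate, channel_labels=tuple(channel_labels),
        spatial_center=spatial_center,
    )


def compensated_injection_waveform(
    template: ErrPTemplate,
    filter_spec=None,
) -> np.ndarray:
    """Pre-compensate the template for the pipeline's causal filter.

    The printed peak values were measured on causally filtered data, and a
    causal band-pass both delays and attenuates a transient, so the raw
    template cannot simply be added to the signal.  The injected waveform
    is built on a fixed basis of Gaussian lobes whose filtered responses
    are linear in the lobe amplitudes; the amplitudes solve a ridge
    least-squares fit to the template shape under *equality constraints*
    that pin the filtered value and slope at every specified peak.  If a
    filter artifact (e.g. the undershoot after the large positivity)
    produces a deeper extremum elsewhere in a peak's search region, that
    location is pinned to 90 % of the peak value and the system re-solved
    (a small active-set loop).  Returns the raw waveform to add at each
    error onset, supported on [0, 1] s.
    """
    from errpscan.preprocess import FilterSpec, causal_bandpass

    if filter_spec is None:
        filter_spec = FilterSpec()
    if len(template.lobes) == 0:
        return np.zeros_like(template.waveform)

    fs = template.sample_rate
    n_support = len(template.waveform)
    t_ext = np.arange(int(round(2.0 * fs))) / fs
    targets = np.array(template.peak_spec)
    n_peaks = len(targets)
    idx = np.round(targets[:, 0] * fs).astype(int)
    d0 = np.concatenate([template.waveform, np.zeros(len(t_ext) - n_support)])

    # each peak's search region: halfway to its neighbours
    lats = targets[:, 0]
    starts = np.concatenate([[max(lats[0] - 0.1, 0.02)], 0.5 * (lats[:-1] + lats[1:])])
    stops = np.concatenate([0.5 * (lats[:-1] + lats[1:]), [1.0]])

    basis_lats = np.arange(0.04, 0.92, 0.02)
    basis_sigma = 0.03
    basis = np.exp(-((t_ext[:, None] - basis_lats[None, :]) ** 2) / (2.0 * basis_sigma**2))
    basis[n_support:, :] = 0.0
    fbasis = causal_bandpass(basis.T, filter_spec, fs).T

    c_eq = np.vstack([fbasis[idx, :], (fbasis[idx + 1, :] - fbasis[idx - 1, :]) * 0.5 * fs * 0.02])
    b_eq = np.concatenate([targets[:, 1], np.zeros(n_peaks)])
    gram = fbasis.T @ fbasis + 1e-3 * np.eye(len(basis_lats))
    proj = fbasis.T @ d0

    def _windowed_extrema(f: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        locs, amps, sample_idx = [], [], []
        for j in range(n_peaks):
            sel = np.flatnonzero((t_ext > starts[j]) & (t_ext < stops[j]))
            seg = f[sel]
            k = int(np.argmax(seg)) if targets[j, 1] >= 0 else int(np.argmin(seg))
            locs.append(t_ext[sel][k])
            amps.append(seg[k])
            sample_idx.append(sel[k])
        return np.array(locs), np.array(amps), np.array(sample_idx)

    extra_rows: list[np.ndarray] = []
    extra_vals: list[float] = []
    amp_coeff = f = None
    for _ in range(12):
        c_full = np.vstack([c_eq] + extra_rows) if extra_rows else c_eq
        b_full = np.concatenate([b_eq, np.array(extra_vals)]) if extra_vals else b_eq
        m = len(b_full)
        kkt = np.block([[gram, c_full.T], [c_full, np.zeros((m, m))]])
        amp_coeff = np.linalg.solve(kkt, np.concatenate([proj, b_full]))[: len(basis_lats)]
        f = fbasis @ amp_coeff
        got_l, got_a, got_i = _windowed_extrema(f)
        bad = np.flatnonzero(
            (np.abs(got_l - targets[:, 0]) > 0.0015) | (np.abs(got_a - targets[:, 1]) > 0.045)
        )
        if len(bad) == 0:
            break
        j = int(bad[0])
        extra_rows.append(fbasis[got_i[j] : got_i[j] + 1, :])
        extra_vals.append(0.9 * targets[j, 1])

    got_l, got_a, _ = _windowed_extrema(f)
    if np.any(np.abs(got_l - targets[:, 0]) > 0.002 + 1e-12) or np.any(
        np.abs(got_a - targets[:, 1]) > 0.05
    ):
        raise RuntimeError("filter pre-compensation did not converge to the peak tolerance")
    return (basis @ amp_coeff)[:n_support]


def jittered_peak_spec(
    peak_spec,
    rng: np.random.Generator,
    amplitude_jitter: float = 0.15,
    latency_jitter: float = 0.020,
) -> tuple[tuple[float, float], ...]:
    """Per-participant template variability: ±15 % amplitude, ±20 ms latency.

    A common latency shift plus small per-peak scaling keeps the peaks
    ordered and resolvable.
    """
    shift = float(rng.uniform(-latency_jitter, latency_jitter))
    out = []
    for lat, amp in peak_spec:
        scale = 1.0 + float(rng.uniform(-amplitude_jitter, amplitude_jitter))
        out.append((lat + shift, amp * scale))
    return tuple(out)


# ---------------------------------------------------------------------------
# Noise / artifacts
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Background and artifact model (invented plumbing, config-exposed).

    The study does not describe its noise statistics; these defaults are a
    generic EEG stand-in: 1/f background at 5 μV RMS per channel with mild
    spatial correlation, plus stereotyped blinks propagating frontally.
    """

    background_rms: float = 5.0          # μV per channel
    spectral_exponent: float = 1.0       # PSD ∝ 1/f^exponent
    spatial_correlation_scale: float = 0.04  # m, Gaussian mixing kernel width
    eog_mixing: np.ndarray | None = None     # (3, n_eeg); None → frontal default
    blink_rate: float = 8.0              # events/minute during the task
    blink_amplitude: float = 150.0       # μV on the vertical EOG
    eog_noise_rms: float = 3.0           # μV sensor noise on EOG channels
    eye_segment_duration: float = 60.0   # s of pre-experiment eye movements
    eye_blink_rate: float = 25.0         # events/minute in the eye segment
    saccade_rate: float = 10.0           # events/minute in the eye segment
    saccade_amplitude: float = 100.0     # μV on horizontal EOG


def default_eog_mixing(channel_labels: tuple[str, ...] = EEG_CHANNELS) -> np.ndarray:
    """Frontally decaying propagation of the three ocular sources into EEG."""
    frontal = gaussian_scalp_pattern(channel_labels, "Fpz", 0.05)
    scales = np.array([0.4, 0.25, 0.25])   # nasion, left canthus, right canthus
    return scales[:, None] * frontal[None, :]


def pink_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    sample_rate: float,
    exponent: float = 1.0,
    f_floor: float = 0.1,
) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise per channel (spectrum flattened < f_floor)."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = scipy.fft.rfft(white, axis=-1)
    f = scipy.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    shaping = np.maximum(f, f_floor) ** (-exponent / 2.0)
    shaping[0] = 0.0
    spec *= shaping
    x = scipy.fft.irfft(spec, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x / rms


def _spatial_mixing_matrix(channel_labels: tuple[str, ...], scale: float) -> np.ndarray:
    if scale <= 0:
        return np.eye(len(channel_labels))
    pos = channel_positions(channel_labels)
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    k = np.exp(-d2 / (2.0 * scale**2))
    return k / np.linalg.norm(k, axis=1, keepdims=True)


def _raised_cosine(duration: float, fs: float) -> np.ndarray:
    n = max(int(round(duration * fs)), 2)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / (n - 1)))


def _add_events(signal_row: np.ndarray, onsets_s: np.ndarray, shape: np.ndarray,
                amplitudes: np.ndarray, fs: float) -> None:
    n = len(signal_row)
    for t0, a in zip(onsets_s, amplitudes):
        i0 = int(round(t0 * fs))
        i1 = min(i0 + len(shape), n)
        if i0 < n:
            signal_row[i0:i1] += a * shape[: i1 - i0]


# ---------------------------------------------------------------------------
# Continuous recording
# ---------------------------------------------------------------------------

@dataclass
class MarkerTable:
    """Event markers: rows of (time_s, kind, trial_index)."""

    frame: pd.DataFrame

    @classmethod
    def from_rows(cls, rows: list[tuple[float, str, int]]) -> "MarkerTable":
        df = pd.DataFrame(rows, columns=["time_s", "kind", "trial_index"])
        return cls(frame=df)

    def validate(self) -> None:
        bad = set(self.frame["kind"]) - set(MARKER_KINDS)
        if bad:
            raise ValueError(f"unknown marker kinds: {sorted(bad)}")
        for ti, grp in self.frame.groupby("trial_index"):
            if not grp["time_s"].is_monotonic_increasing:
                raise ValueError(f"marker times not non-decreasing in trial {ti}")

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.frame[self.frame["kind"] == kind]

    def trial_indices(self) -> np.ndarray:
        return np.sort(self.frame["trial_index"].unique())


@dataclass
class ContinuousRecording:
    """Multichannel EEG+EOG time series with a marker table (μV, float32)."""

    sample_rate: float
    eeg: np.ndarray                       # (n_eeg, n_samples)
    eog: np.ndarray                       # (3, n_samples)
    channel_labels: tuple[str, ...]
    eog_labels: tuple[str, ...]
    markers: MarkerTable
    eye_segment: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.eeg.shape[1] != self.eog.shape[1]:
            raise ValueError("EEG and EOG must have the same number of samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if len(self.markers.frame) and self.markers.frame["time_s"].max() > self.duration:
            raise ValueError("marker times exceed the recording span")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def with_eeg(self, eeg: np.ndarray) -> "ContinuousRecording":
        return replace(self, eeg=eeg)


def synthesize_session(
    plan: SessionPlan,
    template: ErrPTemplate,
    noise: NoiseModel,
    rng_seed: int | np.random.Generator = 0,
    *,
    filter_spec=None,
    inter_trial_gap: float = 1.5,
    settle_gap: float = 3.0,
    onset_delay_mean: float = 0.210,
    onset_delay_sd: float = 0.004,
    secondary_response_delay: float | None = None,
) -> ContinuousRecording:
    """Render a session plan into a continuous EEG/EOG recording.

    Layout: an eye-movement segment (for EOG-model fitting), a settle gap,
    then trials separated by ``inter_trial_gap`` (pre-trial rest plus the
    1.2 s post-trial feedback).  Per error trial an ``error_marker`` is
    placed at the scheduled offset and the ground-truth onset follows at a
    truncated-normal robot delay (0.210 ± 0.004 s); the pre-compensated
    template scaled by the scalp pattern is added at the truth onset.
    ``secondary_response_delay`` optionally injects a half-amplitude copy
    later in each error trial (a stand-in for a robot-resume evoked
    response); it is off by default.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    fs = template.sample_rate
    labels = template.channel_labels

    # -- timeline and markers
    rows: list[tuple[float, str, int]] = []
    onset_truths: list[float] = []
    cursor = noise.eye_segment_duration + settle_gap
    for idx, b, _calib, spec in plan.iter_trials():
        start = cursor
        if spec.planned_duration is None:
            raise ValueError("session plan has unfilled trial durations")
        end = start + spec.planned_duration
        rows.append((start, "trial_start", idx))
        if spec.is_error:
            if spec.error_onset_offset is None:
                raise ValueError("error trial has no error_onset_offset")
            marker = start + spec.error_onset_offset
            delay = -1.0
            while delay <= 0:
                delay = float(rng.normal(onset_delay_mean, onset_delay_sd))
            truth = marker + delay
            rows.append((marker, "error_marker", idx))
            rows.append((truth, "error_onset_truth", idx))
            onset_truths.append(truth)
        else:
            rows.append((end, "target_hit", idx))
        rows.append((end, "trial_end", idx))
        cursor = end + inter_trial_gap
    total = cursor + 2.0
    n = int(round(total * fs))

    # -- background noise
    nc = len(labels)
    if noise.background_rms > 0:
        bg = pink_noise(rng, nc, n, fs, noise.spectral_exponent)
        mix = _spatial_mixing_matrix(labels, noise.spatial_correlation_scale)
        eeg = mix @ bg
        eeg *= noise.background_rms / np.sqrt(np.mean(eeg**2, axis=-1, keepdims=True))
    else:
        eeg = np.zeros((nc, n))

    # -- ocular artifacts
    artifact = np.zeros((3, n))
    blink = _raised_cosine(0.35, fs)
    eye_end = noise.eye_segment_duration

    def _poisson_times(rate_per_min: float, t0: float, t1: float) -> np.ndarray:
        lam = rate_per_min / 60.0 * (t1 - t0)
        k = rng.poisson(lam)
        return np.sort(rng.uniform(t0, t1, size=k))

    blink_times = np.concatenate([
        _poisson_times(noise.eye_blink_rate, 0.0, eye_end),
        _poisson_times(noise.blink_rate, eye_end, total - 1.0),
    ])
    amps = rng.normal(noise.blink_amplitude, 0.1 * noise.blink_amplitude, size=len(blink_times))
    _add_events(artifact[0], blink_times, blink, amps, fs)
    _add_events(artifact[1], blink_times, blink, 0.3 * amps, fs)
    _add_events(artifact[2], blink_times, blink, 0.3 * amps, fs)

    sacc = _raised_cosine(0.4, fs)
    sacc_times = _poisson_times(noise.saccade_rate, 0.0, max(eye_end - 1.0, 0.0))
    sacc_amp = rng.normal(noise.saccade_amplitude, 0.2 * noise.saccade_amplitude, size=len(sacc_times))
    sacc_sign = rng.choice([-1.0, 1.0], size=len(sacc_times))
    _add_events(artifact[1], sacc_times, sacc, sacc_sign * sacc_amp, fs)
    _add_events(artifact[2], sacc_times, sacc, -sacc_sign * sacc_amp, fs)
    _add_events(artifact[0], sacc_times, sacc, 0.2 * sacc_amp, fs)

    mixing = noise.eog_mixing if noise.eog_mixing is not None else default_eog_mixing(labels)
    mixing = np.asarray(mixing, dtype=float)
    if not np.all(np.isfinite(mixing)):
        raise ValueError("eog_mixing coefficients must be finite")
    if mixing.shape != (3, nc):
        raise ValueError(f"eog_mixing must have shape (3, {nc}), got {mixing.shape}")
    eeg += mixing.T @ artifact

    eog = artifact.copy()
    if noise.eog_noise_rms > 0:
        eog += noise.eog_noise_rms * pink_noise(rng, 3, n, fs, noise.spectral_exponent)

    # -- ErrP injection (pre-compensated for the causal band-pass)
    u = compensated_injection_waveform(template, filter_spec)
    for truth in onset_truths:
        i0 = int(round(truth * fs))
        i1 = min(i0 + len(u), n)
        if i1 <= i0:
            raise ValueError("trial schedule exceeds recording capacity")
        eeg[:, i0:i1] += template.spatial_pattern[:, None] * u[: i1 - i0][None, :]
        if secondary_response_delay is not None:
            j0 = int(round((truth + secondary_response_delay) * fs))
            j1 = min(j0 + len(u), n)
            if j0 < n:
                eeg[:, j0:j1] += 0.5 * template.spatial_pattern[:, None] * u[: j1 - j0][None, :]

    markers = MarkerTable.from_rows(rows)
    markers.validate()
    return ContinuousRecording(
        sample_rate=fs,
        eeg=eeg.astype(np.float32),
        eog=eog.astype(np.float32),
        channel_labels=tuple(labels),
        eog_labels=EOG_CHANNELS,
        markers=markers,
        eye_segment=(0.0, eye_end),
    )
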