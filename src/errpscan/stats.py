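"""Grand averages, peak characterisation and pointwise significance.

The ErrP at the frontocentral channel appears (on causally filtered
data) as a small negativity near 0.25 s, a large positivity near 0.35 s
and a broad negativity near 0.57 s after the error onset.  This module
provides the machinery for summarising that morphology: two-level grand
averages with t-based confidence intervals, signed peak extraction inside
search intervals, and pointwise two-sample Wilcoxon rank-sum tests with
Bonferroni correction across time-points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from errpscan.preprocess import EpochSet


@dataclass
class GrandAverage:
    times: np.ndarray
    mean_correct: np.ndarray
    mean_error: np.ndarray
    ci_low_correct: np.ndarray
    ci_high_correct: np.ndarray
    ci_low_error: np.ndarray
    ci_high_error: np.ndarray
    n_units: int
    ci_level: float = 0.95


@dataclass
class SignificanceMask:
    times: np.ndarray
    p_values: np.ndarray
    corrected_alpha: float
    significant: np.ndarray
    significant_intervals: list[tuple[float, float]]


def _t_ci(unit_means: np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
    n = unit_means.shape[0]
    m = unit_means.mean(axis=0)
    sem = unit_means.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = sstats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return m - tcrit * sem, m + tcrit * sem


def unit_class_means(epoch_sets: list[EpochSet], channel: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit mean waveform at one channel for each class.

    Units are typically simulated participants (one EpochSet each); a
    single-session per-trial analysis can pass one EpochSet per trial
    subset instead.  Returns (correct, error) arrays of shape
    (n_units, n_times).
    """
    correct = np.stack([es.class_mean("correct", channel) for es in epoch_sets])
    error = np.stack([es.class_mean("error", channel) for es in epoch_sets])
    return correct, error


def grand_average(
    epoch_sets: list[EpochSet],
    channel: str,
    ci_level: float = 0.95,
) -> GrandAverage:
    """Two-level grand average (per-unit mean, then across units) with t CIs."""
    if len(epoch_sets) < 2:
        raise ValueError("grand average needs at least 2 units (CI undefined for 1)")
    correct, error = unit_class_means(epoch_sets, channel)
    lo_c, hi_c = _t_ci(correct, ci_level)
    lo_e, hi_e = _t_ci(error, ci_level)
    return GrandAverage(
        times=epoch_sets[0].times,
        mean_correct=correct.mean(axis=0),
        mean_error=error.mean(axis=0),
        ci_low_correct=lo_c,
        ci_high_correct=hi_c,
        ci_low_error=lo_e,
        ci_high_error=hi_e,
        n_units=len(epoch_sets),
        ci_level=ci_level,
    )


def find_peaks(
    times: np.ndarray,
    waveform: np.ndarray,
    search_intervals: list[tuple[float, float, str]],
) -> list[tuple[float, float]]:
    """Signed extremum per interval at sample resolution.

    ``search_intervals`` entries are (start s, stop s, polarity) with
    polarity "pos" (maximum) or "neg" (minimum).  On a constant segment
    the extremum is reported at the interval start (first qualifying
    sample).
    """
    out = []
    for start, stop, polarity in search_intervals:
        sel = np.flatnonzero((times > start) & (times < stop))
        if len(sel) == 0:
            raise ValueError(f"search interval ({start}, {stop}) s contains no samples")
        seg = waveform[sel]
        idx = int(np.argmax(seg)) if polarity == "pos" else int(np.argmin(seg))
        out.append((float(times[sel][idx]), float(seg[idx])))
    return out


def pointwise_significance(
    correct_obs: np.ndarray,
    error_obs: np.ndarray,
    times: np.ndarray,
    alpha: float = 0.01,
) -> SignificanceMask:
    """Two-sample rank-sum test at every time-point, Bonferroni corrected.

    ``correct_obs`` / ``error_obs`` are (n_observations, n_times); the
    observations are typically per-participant means (grand-average
    comparison) but may be single trials.  A time-point where all values
    are identical gets p = 1.
    """
    correct_obs = np.atleast_2d(np.asarray(correct_obs, dtype=float))
    error_obs = np.atleast_2d(np.asarray(error_obs, dtype=float))
    if correct_obs.shape[0] < 5 or error_obs.shape[0] < 5:
        raise ValueError("need at least 5 observations per class per time-point")
    n_times = correct_obs.shape[1]
    p = np.ones(n_times)
    for j in range(n_times):
        a, b = correct_obs[:, j], error_obs[:, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            p[j] = 1.0
        else:
            p[j] = sstats.ranksums(a, b).pvalue
    corrected_alpha = alpha / n_times
    sig = p < corrected_alpha
    intervals = []
    j = 0
    while j < n_times:
        if sig[j]:
            k = j
            while k + 1 < n_times and sig[k + 1]:
                k += 1
            intervals.append((float(times[j]), float(times[k])))
            j = k + 1
        else:
            j += 1
    return SignificanceMask(
        times=np.asarray(times),
        p_values=p,
        corrected_alpha=corrected_alpha,
        significant=sig,
        significant_intervals=intervals,
    )


def significance_from_epoch_sets(
    epoch_sets: list[EpochSet],
    channel: str,
    alpha: float = 0.01,
    unit: str = "participants",
) -> SignificanceMask:
    """Convenience wrapper: rank-sum mask from epoch sets.

    ``unit="participants"`` compares per-unit class means (default);
    ``unit="trials"`` pools single trials across the given sets.
    """
    if unit == "participants":
        correct, error = unit_class_means(epoch_sets, channel)
    elif unit == "trials":
        correct = np.concatenate([es.channel(channel)[es.class_labels == "correct"] for es in epoch_sets])
        error = np.concatenate([es.channel(channel)[es.class_labels == "error"] for es in epoch_sets])
    else:
        raise ValueError("unit must be 'participants' or 'trials'")
    return pointwise_significance(correct, error, epoch_sets[0].times, alpha)
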