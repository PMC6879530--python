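"""Sliding-window scanning, the pair rule, trial evaluation and τ calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from errpscan.classifier import (
    PCAModel,
    SLDAModel,
    TrainedDetector,
    WindowSpec,
    predict_error_probability,
)
from errpscan.detection import (
    DEFAULT_TAU_GRID,
    Detection,
    DetectorConfig,
    ProbabilityTrace,
    ThresholdCurve,
    _success_over_grid,
    crossvalidate_thresholds,
    detect,
    evaluate_trial,
    run_online_evaluation,
    scan,
    select_threshold,
    smooth_curve,
)
from errpscan.preprocess import resolve_onsets


def _unit_detector(n_channels=1, fs=500.0):
    """Detector whose score is the mean of the first channel's window."""
    d = n_channels * 225
    comp = np.zeros((1, d))
    comp[0, :225] = 1.0 / np.sqrt(225)
    pca = PCAModel(np.zeros(d), comp, np.array([1.0]))
    lda = SLDAModel(np.array([1.0]), 0.0, 0.5, (0.5, 0.5), np.zeros((2, 1)))
    return TrainedDetector(pca, lda, WindowSpec(), fs, n_channels)


class TestScan:
    def test_six_second_trial_gives_309_windows(self):
        det = _unit_detector()
        sig = np.zeros((1, 3200))
        trace = scan(sig, 500.0, det, 0.0, 6.0)
        assert len(trace.probabilities) == 309
        assert trace.window_end_times[0] == pytest.approx(0.45)
        assert np.allclose(np.diff(trace.window_end_times), 0.018)

    def test_leap_equal_to_segment_gives_single_window(self):
        det = _unit_detector()
        trace = scan(np.zeros((1, 3000)), 500.0, det, 0.0, 6.0, leap=6.0)
        assert len(trace.probabilities) == 1

    def test_segment_shorter_than_window_is_empty(self):
        det = _unit_detector()
        trace = scan(np.zeros((1, 3000)), 500.0, det, 0.0, 0.2)
        assert len(trace.probabilities) == 0

    def test_constant_signal_gives_constant_trace(self):
        det = _unit_detector()
        trace = scan(np.full((1, 2000), 2.5), 500.0, det, 0.0, 4.0)
        assert np.allclose(trace.probabilities, trace.probabilities[0])

    def test_non_sample_multiple_leap_rejected(self):
        with pytest.raises(ValueError, match="sample period"):
            scan(np.zeros((1, 1000)), 500.0, _unit_detector(), 0.0, 2.0, leap=0.0185)

    def test_scan_matches_per_window_posterior(self, preprocessed_noisy, small_detector):
        _, _, cleaned, _ = preprocessed_noisy
        trials = resolve_onsets(cleaned.markers, "calibration")
        row = trials.iloc[0]
        trace = scan(cleaned.eeg, 500.0, small_detector, row.start_s, row.end_s)
        i0 = int(round(row.start_s * 500))
        for k in range(0, len(trace.probabilities), 7):
            win = cleaned.eeg[:, i0 + 9 * k : i0 + 9 * k + 225]
            assert trace.probabilities[k] == pytest.approx(
                predict_error_probability(small_detector, win), abs=1e-9
            )


class TestDetect:
    def test_single_qualifying_pair(self):
        trace = ProbabilityTrace(np.array([0.45, 0.468, 0.486, 0.504]),
                                 np.array([0.2, 0.9, 0.9, 0.3]))
        dets = detect(trace, 0.8)
        assert len(dets) == 1
        assert dets[0].time == pytest.approx(0.486)

    def test_tau_one_never_detects(self):
        trace = ProbabilityTrace(np.arange(4) * 0.018 + 0.45, np.ones(4))
        assert detect(trace, 1.0) == []

    def test_run_of_four_gives_three_detections(self):
        trace = ProbabilityTrace(np.arange(4) * 0.018 + 0.45, np.full(4, 0.9))
        assert len(detect(trace, 0.8)) == 3

    def test_one_per_run_mode(self):
        trace = ProbabilityTrace(np.arange(6) * 0.018 + 0.45,
                                 np.array([0.9, 0.9, 0.9, 0.1, 0.9, 0.9]))
        dets = detect(trace, 0.8, mode="one_per_run")
        assert [pytest.approx(d.time) for d in dets] == [0.468, 0.54]

    @given(
        probs=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=40),
        tau=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_pair_enumeration(self, probs, tau):
        p = np.array(probs)
        times = 0.45 + np.arange(len(p)) * 0.018
        got = [d.time for d in detect(ProbabilityTrace(times, p), tau)]
        expected = [times[i] for i in range(1, len(p)) if p[i] > tau and p[i - 1] > tau]
        assert got == expected

    @given(
        probs=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=40),
        taus=st.tuples(st.floats(0.0, 1.0), st.floats(0.0, 1.0)),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_detection_count_non_increasing_in_tau(self, probs, taus):
        p = np.array(probs)
        trace = ProbabilityTrace(0.45 + np.arange(len(p)) * 0.018, p)
        lo, hi = min(taus), max(taus)
        assert len(detect(trace, hi)) <= len(detect(trace, lo))


class TestEvaluateTrial:
    def test_correct_trial_outcomes(self):
        tn = evaluate_trial([], 0.0, 2.0, 1.0, "correct", "online")
        assert tn.outcome == "TN"
        fp = evaluate_trial([Detection(0.7)], 0.0, 2.0, 1.0, "correct", "online")
        assert fp.outcome == "FP_trial"

    def test_late_detection_calibration_vs_online(self):
        dets = [Detection(3.0)]  # onset 1.0 → 2.0 s after onset
        cal = evaluate_trial(dets, 0.0, 6.0, 1.0, "error", "calibration")
        onl = evaluate_trial(dets, 0.0, 6.0, 1.0, "error", "online")
        assert cal.outcome == "FN_trial"
        assert onl.outcome == "TP"

    def test_pre_onset_detection_blocks_tp(self):
        dets = [Detection(0.8), Detection(1.5)]
        for mode in ("calibration", "online"):
            ev = evaluate_trial(dets, 0.0, 6.0, 1.0, "error", mode)
            assert ev.outcome == "FN_trial"

    def test_in_window_detection_is_tp_in_both_modes(self):
        dets = [Detection(2.0)]  # 1.0 s after onset
        for mode in ("calibration", "online"):
            assert evaluate_trial(dets, 0.0, 6.0, 1.0, "error", mode).outcome == "TP"

    def test_onset_outside_trial_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            evaluate_trial([], 0.0, 2.0, 3.0, "error", "online")

    @given(
        det_times=st.lists(st.floats(0.5, 5.9), max_size=8),
        onset=st.floats(0.8, 1.5),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_calibration_tp_implies_online_tp(self, det_times, onset):
        dets = [Detection(t) for t in sorted(det_times)]
        cal = evaluate_trial(dets, 0.0, 6.0, onset, "error", "calibration")
        onl = evaluate_trial(dets, 0.0, 6.0, onset, "error", "online")
        if cal.outcome == "TP":
            assert onl.outcome == "TP"

    @given(
        probs=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=60),
        onset_frac=st.floats(0.1, 0.9),
        is_error=st.booleans(),
        mode=st.sampled_from(["calibration", "online"]),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_vectorised_grid_matches_detect_then_evaluate(
        self, probs, onset_frac, is_error, mode
    ):
        p = np.array(probs)
        times = 0.45 + np.arange(len(p)) * 0.018
        start, end = 0.0, times[-1] + 0.1
        onset = start + onset_frac * (end - start)
        trace = ProbabilityTrace(times, p)
        cls = "error" if is_error else "correct"
        grid = DEFAULT_TAU_GRID
        fast = _success_over_grid(trace, onset, cls, grid, mode)
        slow = []
        for tau in grid:
            ev = evaluate_trial(detect(trace, tau), start, end, onset, cls, mode)
            slow.append(ev.outcome in ("TP", "TN"))
        assert np.array_equal(fast, np.array(slow))


class TestSmoothing:
    def test_constant_curve_unchanged(self):
        assert np.allclose(smooth_curve(np.full(41, 0.4)), 0.4)

    def test_interior_spike_becomes_one_seventh(self):
        v = np.zeros(41)
        v[20] = 1.0
        assert smooth_curve(v)[20] == pytest.approx(1 / 7)

    def test_window_one_is_identity(self):
        v = np.random.default_rng(0).random(10)
        assert np.array_equal(smooth_curve(v, 1), v)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_curve(np.zeros(10), 4)

    def test_interior_matches_convolution_oracle(self):
        v = np.random.default_rng(1).random(41)
        s = smooth_curve(v, 7)
        oracle = np.convolve(v, np.ones(7) / 7, mode="valid")
        assert np.allclose(s[3:-3], oracle)

    def test_edges_use_shrunken_symmetric_window(self):
        v = np.arange(10.0)
        s = smooth_curve(v, 7)
        assert s[0] == v[0]
        assert s[1] == pytest.approx(v[:3].mean())
        assert s[2] == pytest.approx(v[:5].mean())


class TestSelectThreshold:
    def _curve(self, grid, tpr_s, tnr_s):
        return ThresholdCurve(
            tau_grid=np.asarray(grid, float), tpr=np.asarray(tpr_s, float),
            tnr=np.asarray(tnr_s, float), tpr_smoothed=np.asarray(tpr_s, float),
            tnr_smoothed=np.asarray(tnr_s, float), selected_tau=float("nan"),
        )

    def test_unique_maximum(self):
        c = self._curve([0.1, 0.5, 0.9], [1, 1, 1], [0.2, 0.9, 0.5])
        assert select_threshold(c) == 0.5

    def test_ties_break_to_largest_tau(self):
        c = self._curve([0.1, 0.5, 0.9], [0.5, 0.5, 0.5], [1, 1, 1])
        assert select_threshold(c) == 0.9
        assert not c.flagged

    def test_all_zero_product_flags_session(self):
        c = self._curve([0.1, 0.5, 0.9], [0, 0, 0], [1, 1, 1])
        assert select_threshold(c) == 0.9
        assert c.flagged

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=41),
           st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_exhaustive_argmax_oracle(self, tpr, seed):
        rng = np.random.default_rng(seed)
        tnr = rng.random(len(tpr))
        grid = np.linspace(0, 1, len(tpr))
        c = self._curve(grid, tpr, tnr)
        tau = select_threshold(c)
        product = np.array(tpr) * tnr
        best = max(
            range(len(grid)),
            key=lambda i: (product[i], grid[i]),
        )
        if product.max() > 0:
            assert tau == grid[best]


class TestCrossValidation:
    def test_curve_shape_monotonicity_and_floor(self, preprocessed_noisy, calib_epochs):
        _, _, cleaned, _ = preprocessed_noisy
        trials, epochs = calib_epochs
        curve = crossvalidate_thresholds(cleaned, trials, rng_seed=0, epochs=epochs)
        assert len(curve.tau_grid) == 41
        assert curve.tnr[0] == 0.0                      # τ = 0: every trial fires
        assert np.all(np.diff(curve.tnr) >= -1e-12)     # TNR non-decreasing in τ
        assert np.all((curve.tpr >= 0) & (curve.tpr <= 1))
        assert curve.selected_tau in curve.tau_grid

    def test_deterministic_under_fixed_seed(self, preprocessed_noisy, calib_epochs):
        _, _, cleaned, _ = preprocessed_noisy
        trials, epochs = calib_epochs
        a = crossvalidate_thresholds(cleaned, trials, rng_seed=5, epochs=epochs)
        b = crossvalidate_thresholds(cleaned, trials, rng_seed=5, epochs=epochs)
        assert np.array_equal(a.tpr, b.tpr)
        assert np.array_equal(a.tnr, b.tnr)
        assert a.selected_tau == b.selected_tau

    def test_too_few_trials_per_class_rejected(self, preprocessed_noisy, calib_epochs):
        _, _, cleaned, _ = preprocessed_noisy
        trials, epochs = calib_epochs
        few = trials.head(8).reset_index(drop=True)
        with pytest.raises(ValueError, match="stratified"):
            crossvalidate_thresholds(cleaned, few, rng_seed=0)


class TestOnlineEvaluation:
    def test_tau_one_gives_tnr_one_tpr_zero(self, preprocessed_noisy, small_detector):
        _, _, cleaned, _ = preprocessed_noisy
        trials = resolve_onsets(cleaned.markers, "online")
        trials = trials[trials.trial_index >= 30].reset_index(drop=True)
        rep = run_online_evaluation(small_detector, 1.0, cleaned, trials)
        assert rep.tnr == 1.0
        assert rep.tpr == 0.0

    def test_near_noise_free_session_reaches_perfect_rates(self, small_template):
        from errpscan.classifier import train_detector
        from errpscan.preprocess import extract_epochs, preprocess_recording
        from errpscan.simulate import NoiseModel, make_session_plan, synthesize_session

        noise = NoiseModel(
            background_rms=0.05, blink_rate=0.0, eye_blink_rate=0.0, saccade_rate=0.0,
            eog_noise_rms=0.05, eog_mixing=np.zeros((3, 8)), eye_segment_duration=12.0,
        )
        plan = make_session_plan(block_count=2, calibration_blocks=1, rng_seed=21)
        rec = synthesize_session(plan, small_template, noise, rng_seed=21)
        cleaned, _ = preprocess_recording(rec)
        calib = resolve_onsets(cleaned.markers, "calibration")
        calib = calib[calib.trial_index < 30].reset_index(drop=True)
        detector = train_detector(extract_epochs(cleaned, calib))
        curve = crossvalidate_thresholds(cleaned, calib, rng_seed=2)
        online = resolve_onsets(cleaned.markers, "online")
        online = online[online.trial_index >= 30].reset_index(drop=True)
        rep = run_online_evaluation(detector, curve.selected_tau, cleaned, online)
        assert rep.tpr == 1.0
        assert rep.tnr == 1.0

    def test_detection_times_never_precede_first_window(self, preprocessed_noisy, small_detector):
        _, _, cleaned, _ = preprocessed_noisy
        trials = resolve_onsets(cleaned.markers, "online")
        rep = run_online_evaluation(small_detector, 0.5, cleaned, trials)
        for ev in rep.trials:
            row = trials[trials.trial_index == ev.trial_index].iloc[0]
            for d in ev.detections:
                assert d.time >= row.start_s + 0.45 - 1e-9

    def test_detections_export_schema(self, preprocessed_noisy, small_detector):
        from errpscan.detection import detections_to_frame

        _, _, cleaned, _ = preprocessed_noisy
        trials = resolve_onsets(cleaned.markers, "online")
        rep = run_online_evaluation(small_detector, 0.5, cleaned, trials)
        df = detections_to_frame(rep, trials)
        assert list(df.columns) == ["trial_index", "time_s", "time_rel_onset_s"]
        onsets = trials.set_index("trial_index")["onset_s"]
        for _, row in df.head(20).iterrows():
            assert row.time_rel_onset_s == pytest.approx(row.time_s - onsets[row.trial_index])

    def test_empty_trials_rejected(self, preprocessed_noisy, small_detector):
        _, _, cleaned, _ = preprocessed_noisy
        trials = resolve_onsets(cleaned.markers, "online").head(0)
        with pytest.raises(ValueError, match="no trials"):
            run_online_evaluation(small_detector, 0.5, cleaned, trials)
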