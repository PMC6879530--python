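"""Session-plan constraints, template construction and recording synthesis."""

import numpy as np
import pytest
from scipy import stats

from errpscan.montage import EEG_CHANNELS
from errpscan.preprocess import FilterSpec, causal_bandpass, extract_epochs, resolve_onsets
from errpscan.simulate import (
    DEFAULT_PEAK_SPEC,
    NoiseModel,
    compensated_injection_waveform,
    default_eog_mixing,
    jittered_peak_spec,
    make_block_plan,
    make_errp_template,
    make_session_plan,
    max_error_run,
    max_target_run,
    pink_noise,
    synthesize_session,
)
from tests.conftest import CHANNELS_SMALL


class TestBlockPlan:
    @pytest.mark.parametrize("seed", range(25))
    def test_default_plan_satisfies_paradigm_constraints(self, seed):
        plan = make_block_plan(rng_seed=seed)
        assert plan.n_trials == 30
        assert plan.n_error_trials == 9
        assert max_error_run(plan) <= 2
        assert max_target_run(plan) <= 3
        targets = [t.target for t in plan.trial_specs]
        assert targets.count("left") == targets.count("right") == 15
        for t in plan.trial_specs:
            if t.is_error:
                assert 6.0 <= t.error_distance_de <= 15.0
            else:
                assert t.error_distance_de is None

    def test_zero_error_fraction(self):
        plan = make_block_plan(30, 0.0, 2, 3, rng_seed=1)
        assert plan.n_error_trials == 0

    def test_run_length_two_attained_over_many_plans(self):
        runs = [max_error_run(make_block_plan(rng_seed=s)) for s in range(1, 301)]
        assert max(runs) == 2

    def test_infeasible_constraints_fail_explicitly(self):
        with pytest.raises(RuntimeError, match="redraws"):
            make_block_plan(30, 0.9, 1, 3, rng_seed=0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            make_block_plan(31, 0.30, 2, 3, rng_seed=0)  # odd
        with pytest.raises(ValueError):
            make_block_plan(30, 0.25, 2, 3, rng_seed=0)  # 7.5 error trials
        with pytest.raises(ValueError):
            make_block_plan(30, 1.5, 2, 3, rng_seed=0)


class TestSessionPlan:
    def test_structure_and_timing(self):
        plan = make_session_plan(rng_seed=4)
        assert len(plan.blocks) == 12
        assert plan.calibration_block_count == 8
        assert plan.online_block_count == 4
        n_err = sum(b.n_error_trials for b in plan.blocks)
        assert n_err == 108
        for _, b, calib, spec in plan.iter_trials():
            assert calib == (b < 8)
            if spec.is_error:
                assert spec.planned_duration == 6.0
                assert 0.5 <= spec.error_onset_offset <= 1.3
            else:
                assert 1.6 <= spec.planned_duration <= 2.5

    def test_single_calibration_block(self):
        plan = make_session_plan(block_count=1, calibration_blocks=1, rng_seed=0)
        assert plan.online_block_count == 0

    def test_error_onset_offsets_uniform(self):
        offsets = []
        for s in range(60):
            plan = make_session_plan(rng_seed=1000 + s)
            offsets.extend(
                t.error_onset_offset for b in plan.blocks for t in b.trial_specs if t.is_error
            )
        u = (np.array(offsets) - 0.5) / 0.8
        assert stats.kstest(u, "uniform").pvalue > 0.01


class TestTemplate:
    def test_default_peaks_attained(self, small_template):
        t = small_template.times
        for lat, amp in DEFAULT_PEAK_SPEC:
            sel = (t >= lat - 0.002) & (t <= lat + 0.002)
            target = small_template.waveform[sel]
            assert np.min(np.abs(target - amp)) <= 0.05

    def test_waveform_support(self, small_template):
        assert len(small_template.waveform) == 501
        assert abs(small_template.waveform[0]) < 1e-6
        assert abs(small_template.waveform[-1]) < 1e-3

    def test_empty_peak_list_gives_zero_waveform(self):
        tpl = make_errp_template([], channel_labels=CHANNELS_SMALL)
        assert np.all(tpl.waveform == 0)

    def test_close_peaks_rejected(self):
        with pytest.raises(ValueError, match="40 ms"):
            make_errp_template([(0.30, 1.0), (0.33, -1.0)], channel_labels=CHANNELS_SMALL)

    def test_nonincreasing_latencies_rejected(self):
        with pytest.raises(ValueError):
            make_errp_template([(0.5, 1.0), (0.3, -1.0)], channel_labels=CHANNELS_SMALL)

    def test_spatial_pattern_peaks_at_center(self, small_template):
        i = small_template.channel_labels.index("FCz")
        assert small_template.spatial_pattern[i] == 1.0
        assert np.all(small_template.spatial_pattern <= 1.0)

    @pytest.mark.parametrize("seed", [None, 3, 8])
    def test_compensation_recovers_peaks_after_causal_filter(self, seed):
        if seed is None:
            peaks = DEFAULT_PEAK_SPEC
        else:
            peaks = jittered_peak_spec(DEFAULT_PEAK_SPEC, np.random.default_rng(seed))
        tpl = make_errp_template(peaks, channel_labels=CHANNELS_SMALL)
        u = compensated_injection_waveform(tpl)
        f = causal_bandpass(np.concatenate([u, np.zeros(500)]), FilterSpec(), 500.0)
        t = np.arange(len(f)) / 500.0
        for lat, amp in peaks:
            sel = (t > lat - 0.03) & (t < lat + 0.03)
            ext = f[sel].max() if amp > 0 else f[sel].min()
            assert abs(ext - amp) <= 0.05


class TestNoise:
    def test_pink_noise_unit_rms(self):
        x = pink_noise(np.random.default_rng(0), 4, 30000, 500.0)
        assert np.allclose(np.sqrt((x**2).mean(axis=1)), 1.0, atol=1e-9)

    def test_pink_noise_spectral_slope(self):
        x = pink_noise(np.random.default_rng(1), 1, 2**17, 500.0)[0]
        f, p = stats_periodogram(x)
        sel = (f > 1) & (f < 50)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert -1.3 < slope < -0.7

    def test_background_rms_within_ten_percent(self, noisy_session):
        _, rec = noisy_session
        # quiet stretch away from blinks is not separable; total RMS is checked
        rms = np.sqrt((rec.eeg.astype(float) ** 2).mean(axis=1))
        # EOG mixing adds to frontal channels, so allow the invariant on the
        # background by regenerating without artifacts
        noise = NoiseModel(
            blink_rate=0.0, eye_blink_rate=0.0, saccade_rate=0.0,
            eog_mixing=np.zeros((3, len(CHANNELS_SMALL))), eye_segment_duration=12.0,
        )
        tpl = make_errp_template([], channel_labels=CHANNELS_SMALL)
        plan = make_session_plan(block_count=1, calibration_blocks=1, rng_seed=2)
        clean = synthesize_session(plan, tpl, noise, rng_seed=2)
        rms = np.sqrt((clean.eeg.astype(float) ** 2).mean(axis=1))
        assert np.all(np.abs(rms - 5.0) / 5.0 < 0.10)

    def test_default_eog_mixing_shape_and_finite(self):
        m = default_eog_mixing(EEG_CHANNELS)
        assert m.shape == (3, 61)
        assert np.all(np.isfinite(m))


def stats_periodogram(x):
    from scipy.signal import welch

    return welch(x, fs=500.0, nperseg=8192)


class TestSynthesize:
    def test_marker_to_onset_delay_distribution(self, noisy_session):
        _, rec = noisy_session
        em = rec.markers.of_kind("error_marker").set_index("trial_index")["time_s"]
        tr = rec.markers.of_kind("error_onset_truth").set_index("trial_index")["time_s"]
        d = (tr - em).to_numpy()
        assert np.all((d > 0.19) & (d < 0.23))
        assert abs(d.mean() - 0.210) < 0.003

    def test_every_error_trial_has_both_markers(self, noisy_session):
        plan, rec = noisy_session
        n_err = sum(b.n_error_trials for b in plan.blocks)
        assert len(rec.markers.of_kind("error_marker")) == n_err
        assert len(rec.markers.of_kind("error_onset_truth")) == n_err

    def test_noise_free_epoch_reproduces_template_peaks(self, noisefree_session, small_template):
        _, rec = noisefree_session
        filtered = rec.with_eeg(causal_bandpass(rec.eeg, FilterSpec(), 500.0).astype(np.float32))
        trials = resolve_onsets(rec.markers, "calibration")
        epochs = extract_epochs(filtered, trials)
        err_mean = epochs.class_mean("error", "FCz")
        t = epochs.times
        for lat, amp in small_template.peak_spec:
            sel = (t > lat - 0.03) & (t < lat + 0.03)
            ext = err_mean[sel].max() if amp > 0 else err_mean[sel].min()
            assert abs(ext - amp) <= 0.1

    def test_zero_mixing_leaves_eeg_uncorrelated_with_eog(self, small_template):
        noise = NoiseModel(
            eog_mixing=np.zeros((3, len(CHANNELS_SMALL))), eye_segment_duration=20.0
        )
        plan = make_session_plan(block_count=1, calibration_blocks=1, rng_seed=3)
        rec = synthesize_session(plan, small_template, noise, rng_seed=3)
        eog = rec.eog.astype(float)
        eog -= eog.mean(axis=1, keepdims=True)
        for c in range(rec.eeg.shape[0]):
            y = rec.eeg[c].astype(float)
            y -= y.mean()
            beta, *_ = np.linalg.lstsq(eog.T, y, rcond=None)
            r2 = 1 - ((y - eog.T @ beta) ** 2).sum() / (y**2).sum()
            assert r2 < 0.01

    def test_same_seed_bit_identical(self, small_template):
        plan = make_session_plan(block_count=1, calibration_blocks=1, rng_seed=9)
        noise = NoiseModel(eye_segment_duration=12.0)
        a = synthesize_session(plan, small_template, noise, rng_seed=42)
        b = synthesize_session(plan, small_template, noise, rng_seed=42)
        assert np.array_equal(a.eeg, b.eeg)
        assert np.array_equal(a.eog, b.eog)
        assert a.markers.frame.equals(b.markers.frame)

    def test_secondary_response_toggle_adds_late_energy(self, small_template):
        plan = make_session_plan(block_count=1, calibration_blocks=1, rng_seed=5)
        noise = NoiseModel(
            background_rms=0.0, blink_rate=0.0, eye_blink_rate=0.0, saccade_rate=0.0,
            eog_noise_rms=0.0, eog_mixing=np.zeros((3, len(CHANNELS_SMALL))),
            eye_segment_duration=12.0,
        )
        base = synthesize_session(plan, small_template, noise, rng_seed=5)
        extra = synthesize_session(
            plan, small_template, noise, rng_seed=5, secondary_response_delay=1.2
        )
        assert np.abs(extra.eeg - base.eeg).max() > 1.0
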