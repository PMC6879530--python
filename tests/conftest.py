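"""Shared fixtures: small synthetic sessions kept cheap for fast tests.

The full-scale benchmark uses 61 channels and 12 blocks; unit tests run
on an 8-channel frontocentral subset with 1–2 blocks, which exercises
every code path at a fraction of the cost.
"""

import numpy as np
import pytest

from errpscan.detection import DetectorConfig
from errpscan.preprocess import FilterSpec, preprocess_recording, resolve_onsets, extract_epochs
from errpscan.simulate import (
    NoiseModel,
    make_errp_template,
    make_session_plan,
    synthesize_session,
)

CHANNELS_SMALL = ("Fz", "FC1", "FCz", "FC2", "Cz", "CPz", "Pz", "Oz")


@pytest.fixture(scope="session")
def small_template():
    return make_errp_template(channel_labels=CHANNELS_SMALL)


@pytest.fixture(scope="session")
def noisefree_session(small_template):
    """Two-block session with zero noise and zero EOG mixing."""
    plan = make_session_plan(block_count=2, calibration_blocks=1, rng_seed=11)
    noise = NoiseModel(
        background_rms=0.0, blink_rate=0.0, eye_blink_rate=0.0, saccade_rate=0.0,
        eog_noise_rms=0.0, eog_mixing=np.zeros((3, len(CHANNELS_SMALL))),
        eye_segment_duration=12.0,
    )
    rec = synthesize_session(plan, small_template, noise, rng_seed=11)
    return plan, rec


@pytest.fixture(scope="session")
def noisy_session(small_template):
    """Two-block session (1 calibration + 1 online) with default-level noise."""
    plan = make_session_plan(block_count=2, calibration_blocks=1, rng_seed=7)
    noise = NoiseModel(eye_segment_duration=30.0)
    rec = synthesize_session(plan, small_template, noise, rng_seed=7)
    return plan, rec


@pytest.fixture(scope="session")
def preprocessed_noisy(noisy_session):
    plan, rec = noisy_session
    cleaned, model = preprocess_recording(rec, FilterSpec())
    return plan, rec, cleaned, model


@pytest.fixture(scope="session")
def calib_epochs(preprocessed_noisy):
    _, _, cleaned, _ = preprocessed_noisy
    trials = resolve_onsets(cleaned.markers, "calibration")
    trials = trials[trials["trial_index"] < 30].reset_index(drop=True)
    return trials, extract_epochs(cleaned, trials)


@pytest.fixture(scope="session")
def small_detector(calib_epochs):
    from errpscan.classifier import train_detector

    _, epochs = calib_epochs
    return train_detector(epochs)
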