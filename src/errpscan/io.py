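"""Serialisation: native recording container, plans, epochs, detectors.

The native recording container is a directory holding

* ``header.json`` — sample rate, channel labels, units (μV), shapes;
* ``eeg.f32`` / ``eog.f32`` — raw signal, little-endian float32,
  channel-major (C contiguous rows);
* ``markers.csv`` — columns ``time_s,kind,trial_index``.

Recordings are stored as float32 in memory too, so a write→read round
trip is bit-exact.  BrainVision import (``.vhdr``/``.eeg``/``.vmrk``) is
available through MNE, mapping its marker stream onto the marker table.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from errpscan.classifier import PCAModel, SLDAModel, TrainedDetector, WindowSpec
from errpscan.preprocess import EpochSet
from errpscan.simulate import (
    BlockPlan,
    ContinuousRecording,
    MarkerTable,
    SessionPlan,
    TrialSpec,
)


# ---------------------------------------------------------------------------
# Native recording container
# ---------------------------------------------------------------------------

def save_recording(recording: ContinuousRecording, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "sample_rate": recording.sample_rate,
        "channel_labels": list(recording.channel_labels),
        "eog_labels": list(recording.eog_labels),
        "units": "uV",
        "n_samples": recording.n_samples,
        "eye_segment": list(recording.eye_segment) if recording.eye_segment else None,
    }
    (path / "header.json").write_text(json.dumps(header, indent=1, sort_keys=True))
    recording.eeg.astype("<f4").tofile(path / "eeg.f32")
    recording.eog.astype("<f4").tofile(path / "eog.f32")
    # %.17g round-trips float64 exactly
    recording.markers.frame.to_csv(path / "markers.csv", index=False, float_format="%.17g")


def load_recording(path: str | Path) -> ContinuousRecording:
    path = Path(path)
    header = json.loads((path / "header.json").read_text())
    n = header["n_samples"]
    n_eeg = len(header["channel_labels"])
    eeg = np.fromfile(path / "eeg.f32", dtype="<f4").reshape(n_eeg, n)
    eog = np.fromfile(path / "eog.f32", dtype="<f4").reshape(len(header["eog_labels"]), n)
    markers = MarkerTable(frame=pd.read_csv(path / "markers.csv", float_precision="round_trip"))
    eye = header["eye_segment"]
    return ContinuousRecording(
        sample_rate=header["sample_rate"],
        eeg=eeg,
        eog=eog,
        channel_labels=tuple(header["channel_labels"]),
        eog_labels=tuple(header["eog_labels"]),
        markers=markers,
        eye_segment=tuple(eye) if eye else None,
    )


# ---------------------------------------------------------------------------
# Session plans (JSON)
# ---------------------------------------------------------------------------

def session_plan_to_json(plan: SessionPlan) -> str:
    return json.dumps(
        {
            "calibration_block_count": plan.calibration_block_count,
            "blocks": [
                {
                    "block_index": b.block_index,
                    "trials": [dataclasses.asdict(t) for t in b.trial_specs],
                }
                for b in plan.blocks
            ],
        },
        indent=1,
        sort_keys=True,
    )


def session_plan_from_json(text: str) -> SessionPlan:
    raw = json.loads(text)
    blocks = [
        BlockPlan(
            trial_specs=[TrialSpec(**t) for t in b["trials"]],
            block_index=b["block_index"],
        )
        for b in raw["blocks"]
    ]
    return SessionPlan(blocks=blocks, calibration_block_count=raw["calibration_block_count"])


def save_session_plan(plan: SessionPlan, path: str | Path) -> None:
    Path(path).write_text(session_plan_to_json(plan))


def load_session_plan(path: str | Path) -> SessionPlan:
    return session_plan_from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Epoch sets
# ---------------------------------------------------------------------------

def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "shape": list(epochs.epochs.shape),
        "onset_index": epochs.onset_index,
        "class_labels": epochs.class_labels.tolist(),
        "trial_indices": [int(t) for t in epochs.trial_indices],
        "sample_rate": epochs.sample_rate,
        "channel_labels": list(epochs.channel_labels),
        "epoch_interval": list(epochs.epoch_interval),
    }
    (path / "epochs.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    epochs.epochs.astype("<f4").tofile(path / "epochs.f32")


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    meta = json.loads((path / "epochs.json").read_text())
    data = np.fromfile(path / "epochs.f32", dtype="<f4").reshape(meta["shape"])
    return EpochSet(
        epochs=data,
        onset_index=meta["onset_index"],
        class_labels=np.array(meta["class_labels"]),
        trial_indices=np.array(meta["trial_indices"]),
        sample_rate=meta["sample_rate"],
        channel_labels=tuple(meta["channel_labels"]),
        epoch_interval=tuple(meta["epoch_interval"]),
    )


# ---------------------------------------------------------------------------
# Trained detectors
# ---------------------------------------------------------------------------

def save_detector(detector: TrainedDetector, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "window": {"offset": detector.window.offset, "length": detector.window.length},
        "sample_rate": detector.sample_rate,
        "channel_count": detector.channel_count,
        "variance_threshold": detector.pca.variance_threshold,
        "shrinkage_gamma": detector.lda.shrinkage_gamma,
        "bias": detector.lda.bias,
        "class_priors": list(detector.lda.class_priors),
        "calibration_scale": detector.lda.calibration_scale,
        "calibration_offset": detector.lda.calibration_offset,
    }
    (path / "detector.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    np.savez(
        path / "arrays.npz",
        mean_vector=detector.pca.mean_vector,
        components=detector.pca.components,
        explained_variance_ratio=detector.pca.explained_variance_ratio,
        weight_vector=detector.lda.weight_vector,
        class_means=detector.lda.class_means,
    )


def load_detector(path: str | Path) -> TrainedDetector:
    path = Path(path)
    meta = json.loads((path / "detector.json").read_text())
    arrays = np.load(path / "arrays.npz")
    pca = PCAModel(
        mean_vector=arrays["mean_vector"],
        components=arrays["components"],
        explained_variance_ratio=arrays["explained_variance_ratio"],
        variance_threshold=meta["variance_threshold"],
    )
    lda = SLDAModel(
        weight_vector=arrays["weight_vector"],
        bias=meta["bias"],
        shrinkage_gamma=meta["shrinkage_gamma"],
        class_priors=tuple(meta["class_priors"]),
        class_means=arrays["class_means"],
        calibration_scale=meta.get("calibration_scale", 1.0),
        calibration_offset=meta.get("calibration_offset", 0.0),
    )
    return TrainedDetector(
        pca=pca,
        lda=lda,
        window=WindowSpec(**meta["window"]),
        sample_rate=meta["sample_rate"],
        channel_count=meta["channel_count"],
    )


# ---------------------------------------------------------------------------
# BrainVision import (optional)
# ---------------------------------------------------------------------------

def read_brainvision(
    vhdr_path: str | Path,
    eog_labels: tuple[str, ...] = ("EOG-nasion", "EOG-left", "EOG-right"),
    marker_map: dict[str, str] | None = None,
    eye_segment: tuple[float, float] | None = None,
) -> ContinuousRecording:
    """Import a BrainVision recording, mapping its marker descriptions.

    ``marker_map`` maps BrainVision annotation descriptions (e.g.
    ``"Stimulus/S  1"``) onto the native marker kinds; unmapped
    annotations are dropped.  Trial indices are assigned by counting
    ``trial_start`` markers; markers preceding the first trial get −1.
    """
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE volts → μV
    labels = raw.ch_names
    eog_idx = [labels.index(lab) for lab in eog_labels if lab in labels]
    eeg_idx = [i for i in range(len(labels)) if i not in eog_idx]
    marker_map = marker_map or {}
    rows = []
    trial = -1
    for ann in raw.annotations:
        kind = marker_map.get(ann["description"])
        if kind is None:
            continue
        if kind == "trial_start":
            trial += 1
        rows.append((float(ann["onset"]), kind, trial))
    return ContinuousRecording(
        sample_rate=float(raw.info["sfreq"]),
        eeg=data[eeg_idx].astype(np.float32),
        eog=data[eog_idx].astype(np.float32) if eog_idx else np.zeros((3, data.shape[1]), np.float32),
        channel_labels=tuple(labels[i] for i in eeg_idx),
        eog_labels=tuple(labels[i] for i in eog_idx) or ("EOG-nasion", "EOG-left", "EOG-right"),
        markers=MarkerTable.from_rows(rows),
        eye_segment=eye_segment,
    )
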