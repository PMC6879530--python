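"""Electrode montage helpers.

The recording layout emulates a 61-channel actiCAP arrangement on the
extended 10-10 system (ground AFz, reference right mastoid, both excluded
from the signal channels) plus three EOG electrodes: one above the nasion
and one below each outer canthus.

Positions come from MNE's built-in idealised 10-05 montage and are used
only to shape spatial patterns (ErrP topography, noise correlation, blink
propagation); no inverse modelling is done.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

#: Default 61-channel EEG layout (frontal to occipital rows).
EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

#: Frontocentral reference channel for ErrP waveforms.
FRONTOCENTRAL: str = "FCz"

#: EOG electrode labels (above nasion, below left/right outer canthus).
EOG_CHANNELS: tuple[str, ...] = ("EOG-nasion", "EOG-left", "EOG-right")


@lru_cache(maxsize=1)
def _montage_positions() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    return {k: np.asarray(v) for k, v in montage.get_positions()["ch_pos"].items()}


def channel_positions(labels: tuple[str, ...] | list[str]) -> np.ndarray:
    """Return (n, 3) head-frame positions in metres for 10-10 labels."""
    pos = _montage_positions()
    missing = [lab for lab in labels if lab not in pos]
    if missing:
        raise ValueError(f"labels not in the 10-05 montage: {missing}")
    return np.stack([pos[lab] for lab in labels])


def gaussian_scalp_pattern(
    labels: tuple[str, ...] | list[str],
    center: str,
    width: float,
) -> np.ndarray:
    """Gaussian spatial weighting over the montage, 1.0 at ``center``.

    ``width`` is the Gaussian sigma in metres over Euclidean electrode
    distance.  Used for the ErrP topography stand-in and for artifact
    propagation profiles.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    pos = channel_positions(labels)
    c = channel_positions([center])[0]
    d2 = np.sum((pos - c) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * width**2))
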