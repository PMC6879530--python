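"""Single-window ErrP classifier: amplitude features → PCA(99 %) → shrinkage LDA.

The features of a trial are the raw amplitudes of every EEG channel at
every sample inside a 450 ms window starting 300 ms after the trial's
onset (error onset for error trials, virtual onset for correct trials):
61 channels × 225 samples = 13 725 features at 500 Hz.  PCA keeps the
leading components explaining 99 % of the variance; a two-class LDA with
the pooled covariance shrunk toward a scaled identity (Ledoit–Wolf γ by
default) yields the posterior probability that a window contains an ErrP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.decomposition import PCA as _SkPCA

from errpscan.preprocess import EpochSet

PROBABILITY_FLOOR = 1e-12   # posteriors are clipped away from exactly 0


@dataclass
class WindowSpec:
    """Feature window relative to the trial onset (seconds)."""

    offset: float = 0.300
    length: float = 0.450

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("window offset must be non-negative")
        if self.length <= 0:
            raise ValueError("window length must be positive")

    def n_samples(self, sample_rate: float) -> int:
        return int(round(self.length * sample_rate))


def extract_training_features(
    epochs: EpochSet, window: WindowSpec
) -> tuple[np.ndarray, np.ndarray]:
    """One channel-major flattened feature row per trial, plus class labels.

    Rows are ``epoch[:, i0:i1].ravel()`` with the half-open sample window
    ``[onset + offset, onset + offset + length)``.
    """
    fs = epochs.sample_rate
    i0 = epochs.onset_index + int(round(window.offset * fs))
    i1 = i0 + window.n_samples(fs)
    n_total = epochs.epochs.shape[-1]
    if i0 < 0 or i1 > n_total or i1 <= i0:
        raise ValueError(
            f"window [{window.offset}, {window.offset + window.length}) s falls outside "
            f"the epoch interval {epochs.epoch_interval}"
        )
    x = epochs.epochs[:, :, i0:i1]
    features = np.ascontiguousarray(x, dtype=float).reshape(x.shape[0], -1)
    return features, epochs.class_labels.copy()


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    mean_vector: np.ndarray
    components: np.ndarray              # (k, d), row-orthonormal
    explained_variance_ratio: np.ndarray
    variance_threshold: float = 0.99

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(features: np.ndarray, variance_threshold: float = 0.99) -> PCAModel:
    """Centred PCA keeping the smallest k with cumulative EVR ≥ threshold.

    With threshold 1.0 all components up to the rank of the centred data
    are kept.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain non-finite values")
    if not 0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    if np.all(features == features[0]):
        raise ValueError("features have zero variance")
    pca = _SkPCA(n_components=None, svd_solver="full")
    pca.fit(features)
    sv = pca.singular_values_
    rank = int(np.sum(sv > sv[0] * max(features.shape) * np.finfo(float).eps))
    evr = pca.explained_variance_ratio_
    if variance_threshold >= 1.0:
        k = rank
    else:
        k = int(np.searchsorted(np.cumsum(evr), variance_threshold) + 1)
        k = min(k, rank)
    return PCAModel(
        mean_vector=pca.mean_,
        components=pca.components_[:k].copy(),
        explained_variance_ratio=evr[:k].copy(),
        variance_threshold=variance_threshold,
    )


def project(pca: PCAModel, features: np.ndarray) -> np.ndarray:
    """(x − mean) · componentsᵀ for one row or a stack of rows."""
    features = np.asarray(features, dtype=float)
    if features.shape[-1] != pca.mean_vector.shape[0]:
        raise ValueError(
            f"feature dimension {features.shape[-1]} does not match PCA input "
            f"dimension {pca.mean_vector.shape[0]}"
        )
    return (features - pca.mean_vector) @ pca.components.T


# ---------------------------------------------------------------------------
# Shrinkage LDA
# ---------------------------------------------------------------------------

@dataclass
class SLDAModel:
    """Two-class LDA with Σ̂ = (1−γ)Σ + γ·(tr Σ / k)·I.

    The posterior for the error class is a logistic function of the
    linear score s = wᵀz + b.  When features outnumber trials the raw
    shared-covariance posterior σ(s) is badly over-confident (the
    estimated covariance is too small along overfit directions), so the
    score is passed through a Platt map σ(A·s + B) fitted on
    cross-validated scores of the training data; A = 1, B = 0 recovers
    the plain LDA posterior.  The map is monotone — it changes no
    decision ranking, only the probability scale.
    """

    weight_vector: np.ndarray
    bias: float
    shrinkage_gamma: float
    class_priors: tuple[float, float]       # (correct, error)
    class_means: np.ndarray = field(default=None, repr=False)  # (2, k), diagnostics
    calibration_scale: float = 1.0          # Platt A
    calibration_offset: float = 0.0         # Platt B


def _fit_slda_core(
    z: np.ndarray, y: np.ndarray, shrinkage: str | float
) -> tuple[np.ndarray, float, float, tuple[float, float], np.ndarray]:
    n0, n1 = int(np.sum(~y)), int(np.sum(y))
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to fit LDA")
    mu0 = z[~y].mean(axis=0)
    mu1 = z[y].mean(axis=0)
    centred = z.copy()
    centred[~y] -= mu0
    centred[y] -= mu1

    if shrinkage == "auto":
        gamma = float(ledoit_wolf_shrinkage(centred, assume_centered=True))
    else:
        gamma = float(shrinkage)
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("fixed shrinkage γ must lie in [0, 1]")

    k = z.shape[1]
    cov = centred.T @ centred / len(z)
    nu = np.trace(cov) / k
    shrunk = (1.0 - gamma) * cov
    shrunk[np.diag_indices(k)] += gamma * nu
    w = np.linalg.solve(shrunk, mu1 - mu0)
    priors = (n0 / len(z), n1 / len(z))
    bias = float(-0.5 * w @ (mu0 + mu1) + np.log(priors[1] / priors[0]))
    return w, bias, gamma, priors, np.stack([mu0, mu1])


def _platt_calibration(
    z: np.ndarray, y: np.ndarray, shrinkage: str | float, folds: int = 5
) -> tuple[float, float]:
    """Platt scaling on out-of-fold LDA scores (stratified, deterministic)."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    if min(int(np.sum(y)), int(np.sum(~y))) < folds:
        return 1.0, 0.0
    scores = np.empty(len(z))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=0)
    for train_idx, test_idx in skf.split(z, y):
        w, b, *_ = _fit_slda_core(z[train_idx], y[train_idx], shrinkage)
        scores[test_idx] = z[test_idx] @ w + b
    lr = LogisticRegression(C=1e6).fit(scores[:, None], y)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def fit_slda(
    reduced: np.ndarray,
    labels: np.ndarray,
    shrinkage: str | float = "auto",
    calibration: str | None = "cv",
) -> SLDAModel:
    """Fit shrinkage LDA on PCA-reduced features.

    ``labels`` may be the string classes ("correct"/"error") or booleans
    with True = error.  ``shrinkage="auto"`` uses the Ledoit–Wolf rule on
    the class-centred data; a float in [0, 1] fixes γ.
    ``calibration="cv"`` (default) Platt-scales the score on 5-fold
    out-of-fold predictions so the posterior is an honest probability;
    ``calibration=None`` keeps the raw shared-covariance posterior.
    """
    z = np.asarray(reduced, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        y = y == "error"
    y = y.astype(bool)
    w, bias, gamma, priors, means = _fit_slda_core(z, y, shrinkage)
    if calibration == "cv":
        a, b = _platt_calibration(z, y, shrinkage)
    elif calibration is None:
        a, b = 1.0, 0.0
    else:
        raise ValueError(f"unknown calibration mode {calibration!r}")
    return SLDAModel(
        weight_vector=w,
        bias=bias,
        shrinkage_gamma=gamma,
        class_priors=priors,
        class_means=means,
        calibration_scale=a,
        calibration_offset=b,
    )


def slda_error_posterior(model: SLDAModel, reduced: np.ndarray) -> np.ndarray:
    """P(error | z) = σ(A·(wᵀz + b) + B), clipped away from exactly 0."""
    score = np.asarray(reduced, dtype=float) @ model.weight_vector + model.bias
    score = model.calibration_scale * score + model.calibration_offset
    return np.clip(expit(score), PROBABILITY_FLOOR, 1.0)


# ---------------------------------------------------------------------------
# Composed detector
# ---------------------------------------------------------------------------

@dataclass
class TrainedDetector:
    """PCA basis + shrinkage-LDA model + window spec, ready for scanning."""

    pca: PCAModel
    lda: SLDAModel
    window: WindowSpec
    sample_rate: float
    channel_count: int

    def __post_init__(self) -> None:
        expected = self.channel_count * self.window.n_samples(self.sample_rate)
        if self.pca.mean_vector.shape[0] != expected:
            raise ValueError(
                f"PCA input dimension {self.pca.mean_vector.shape[0]} does not equal "
                f"channels × window samples = {expected}"
            )

    def linear_functional(self) -> tuple[np.ndarray, float]:
        """Collapse PCA + LDA into a single linear score on a raw window.

        Returns (V, c) with V shaped (channels, window samples) such that
        σ(Σ V·window + c) equals :func:`predict_error_probability` for
        every window — used by the asynchronous scanner.
        """
        a = self.lda.calibration_scale
        v = a * (self.pca.components.T @ self.lda.weight_vector)
        c = a * self.lda.bias - float(self.pca.mean_vector @ v) + self.lda.calibration_offset
        return v.reshape(self.channel_count, -1), c


def predict_error_probability(detector: TrainedDetector, window: np.ndarray) -> float:
    """Posterior P(error) for one raw (channels × samples) window."""
    window = np.asarray(window, dtype=float)
    expected = (detector.channel_count, detector.window.n_samples(detector.sample_rate))
    if window.shape != expected:
        raise ValueError(f"window shape {window.shape} does not match detector {expected}")
    z = project(detector.pca, window.ravel())
    return float(slda_error_posterior(detector.lda, z))


def train_detector(
    epochs: EpochSet,
    window: WindowSpec | None = None,
    variance_threshold: float = 0.99,
    shrinkage: str | float = "auto",
    calibration: str | None = "cv",
) -> TrainedDetector:
    """Fit the full feature → PCA → shrinkage-LDA stack on an epoch set."""
    window = window or WindowSpec()
    x, y = extract_training_features(epochs, window)
    pca = fit_pca(x, variance_threshold)
    lda = fit_slda(project(pca, x), y, shrinkage, calibration)
    return TrainedDetector(
        pca=pca,
        lda=lda,
        window=window,
        sample_rate=epochs.sample_rate,
        channel_count=epochs.epochs.shape[1],
    )
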