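"""Autoencoder-based anomaly detection for microbubble RF vectors.

The detector learns the acoustic response of individual microbubbles by
reconstructing their 160-sample RF segments through an LSTM autoencoder, and
flags test vectors whose mean squared reconstruction error exceeds a threshold
set just above the maximum error seen in training.  Echoes from clustered
agents, with their higher amplitude and elevated subharmonic content, lie off
the learned manifold and reconstruct poorly.

Two estimator classes follow scikit-learn conventions (``fit`` /
``transform`` / ``predict``, trailing-underscore fitted attributes) and
compose with sklearn pipelines; the module-level functions are thin wrappers
over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from ._lstm import LSTMAutoencoder

__all__ = [
    "ModelConfig",
    "NormalizationParams",
    "ReconstructionResult",
    "GlobalMinMaxScaler",
    "LSTMAnomalyDetector",
    "normalize",
    "train_autoencoder",
    "reconstruction_error",
    "compute_threshold",
    "classify",
    "separate",
]

VECTOR_LEN = 160


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the LSTM autoencoder detector.

    ``encoder_units`` are three strictly decreasing LSTM widths; the decoder
    mirrors them (``decoder_units`` may be given explicitly but must be the
    exact reverse).  The output nonlinearity is a time-distributed sigmoid,
    which is why inputs must be scaled to [0, 1].
    """

    encoder_units: tuple[int, int, int] = (32, 16, 8)
    decoder_units: Optional[tuple[int, int, int]] = None
    activation: str = "sigmoid"
    learning_rate: float = 3e-3
    batch_size: int = 256
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        eu = tuple(int(u) for u in self.encoder_units)
        if len(eu) != 3 or not (eu[0] > eu[1] > eu[2] > 0):
            raise ValueError("encoder_units must be three strictly decreasing widths")
        object.__setattr__(self, "encoder_units", eu)
        mirror = tuple(reversed(eu))
        if self.decoder_units is None:
            object.__setattr__(self, "decoder_units", mirror)
        elif tuple(int(u) for u in self.decoder_units) != mirror:
            raise ValueError("decoder_units must mirror encoder_units in reverse")
        if self.activation != "sigmoid":
            raise ValueError("only the sigmoid output activation is supported")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size must be >= 1 and learning_rate > 0")


@dataclass(frozen=True)
class NormalizationParams:
    """Global min/max of the training values (training set only, no leakage)."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError("degenerate data: hi must exceed lo")


@dataclass(frozen=True)
class ReconstructionResult:
    """Per-vector anomaly decision."""

    error: float
    threshold: float
    is_anomaly: bool
    source_frame: int = -1

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("reconstruction error must be nonnegative")
        if self.is_anomaly != (self.error > self.threshold):
            raise ValueError("is_anomaly must equal (error > threshold)")


class GlobalMinMaxScaler(TransformerMixin, BaseEstimator):
    """Scale by the single global min/max of the training values.

    Unlike per-feature min-max scaling, one (lo, hi) pair is shared by all 160
    positions so the scaling preserves the waveform shape; values outside the
    training range are clipped to [0, 1] on transform.
    """

    def __init__(self, clip: bool = True):
        self.clip = clip

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=False, dtype=np.float64)
        if X.size == 0:
            raise ValueError("cannot fit scaler on empty data")
        lo, hi = float(np.min(X)), float(np.max(X))
        if not hi > lo:
            raise ValueError("degenerate data: global max equals global min")
        self.lo_ = lo
        self.hi_ = hi
        return self

    def transform(self, X):
        check_is_fitted(self, "lo_")
        X = check_array(X, ensure_2d=False, dtype=np.float64)
        out = (X - self.lo_) / (self.hi_ - self.lo_)
        if self.clip:
            out = np.clip(out, 0.0, 1.0)
        return out

    def inverse_transform(self, X):
        check_is_fitted(self, "lo_")
        X = check_array(X, ensure_2d=False, dtype=np.float64)
        return X * (self.hi_ - self.lo_) + self.lo_

    @property
    def params_(self) -> NormalizationParams:
        check_is_fitted(self, "lo_")
        return NormalizationParams(lo=self.lo_, hi=self.hi_)


class LSTMAnomalyDetector(OutlierMixin, BaseEstimator):
    """One-class anomaly detector: LSTM autoencoder + max-train-error threshold.

    Parameters
    ----------
    encoder_units : three strictly decreasing LSTM widths (decoder mirrored).
    margin : multiplicative threshold margin (>= 1); the anomaly threshold is
        ``margin * max(training reconstruction errors)``.
    normalize : fit a :class:`GlobalMinMaxScaler` on the training data and
        apply it to all inputs.  Pass False if the data are already in [0, 1].

    Fitted attributes
    -----------------
    model_ : the trained :class:`~clusterecho._lstm.LSTMAutoencoder`.
    scaler_ : fitted scaler (or None when ``normalize=False``).
    train_errors_ : per-vector training reconstruction errors.
    threshold_ : anomaly threshold.
    """

    def __init__(
        self,
        encoder_units: Sequence[int] = (32, 16, 8),
        learning_rate: float = 3e-3,
        batch_size: int = 256,
        epochs: int = 20,
        margin: float = 1.05,
        normalize: bool = True,
        seed: int = 0,
    ):
        self.encoder_units = encoder_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.margin = margin
        self.normalize = normalize
        self.seed = seed

    def _validate(self, X) -> np.ndarray:
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != VECTOR_LEN:
            raise ValueError(f"expected vectors of length {VECTOR_LEN}, got {X.shape[1]}")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        if X.shape[0] == 0:
            raise ValueError("training set is empty")
        if self.margin < 1.0:
            raise ValueError("margin must be >= 1")
        if self.normalize:
            self.scaler_ = GlobalMinMaxScaler().fit(X)
            Xs = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Xs = X
        cfg = ModelConfig(
            encoder_units=tuple(self.encoder_units),
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=self.seed,
        )
        self.model_, self.train_errors_ = train_autoencoder(Xs, cfg)
        self.threshold_ = compute_threshold(self.train_errors_, margin=self.margin)
        return self

    def _scaled(self, X) -> np.ndarray:
        X = self._validate(X)
        return self.scaler_.transform(X) if self.scaler_ is not None else X

    def score_samples(self, X) -> np.ndarray:
        """Mean squared reconstruction error per vector (higher = more anomalous)."""
        check_is_fitted(self, "model_")
        return self.model_.reconstruction_errors(self._scaled(X))

    def decision_function(self, X) -> np.ndarray:
        """Positive for anomalies: ``error - threshold_``."""
        return self.score_samples(X) - self.threshold_

    def predict(self, X) -> np.ndarray:
        """Boolean anomaly flags (strict ``error > threshold_``)."""
        return self.score_samples(X) > self.threshold_


# ---------------------------------------------------------------------------
# Functional surface (thin wrappers over the estimators)
# ---------------------------------------------------------------------------

def normalize(
    vectors: np.ndarray, params: Optional[NormalizationParams] = None
) -> tuple[np.ndarray, NormalizationParams]:
    """Global min-max scale to [0, 1]; fit on first (training) call.

    With ``params`` given, reuses them and clips to [0, 1]; without, fits the
    (lo, hi) pair from ``vectors``.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    scaler = GlobalMinMaxScaler()
    if params is None:
        if vectors.size == 0:
            raise ValueError("cannot fit normalization on empty data")
        scaler.fit(vectors)
    else:
        scaler.lo_, scaler.hi_ = params.lo, params.hi
    return scaler.transform(vectors), scaler.params_


def train_autoencoder(
    train: np.ndarray, cfg: ModelConfig
) -> tuple[LSTMAutoencoder, np.ndarray]:
    """Train the autoencoder on scaled vectors; return (model, train errors)."""
    train = np.asarray(train, dtype=np.float64)
    if train.ndim != 2 or train.shape[0] == 0:
        raise ValueError("training set must be a non-empty (n, 160) array")
    if train.shape[1] != VECTOR_LEN:
        raise ValueError(f"expected vectors of length {VECTOR_LEN}")
    if np.min(train) < -1e-9 or np.max(train) > 1.0 + 1e-9:
        raise ValueError("training vectors must be scaled to [0, 1]")
    model = LSTMAutoencoder(
        encoder_units=cfg.encoder_units,
        seq_len=VECTOR_LEN,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        seed=cfg.seed,
    )
    model.fit(train)
    return model, model.reconstruction_errors(train)


def reconstruction_error(model: LSTMAutoencoder, vector: np.ndarray) -> float:
    """Mean squared error between one scaled vector and its reconstruction."""
    vector = np.asarray(vector, dtype=np.float64)
    if vector.shape != (VECTOR_LEN,):
        raise ValueError(f"vector must have length {VECTOR_LEN}")
    return float(model.reconstruction_errors(vector[None, :])[0])


def compute_threshold(train_errors: np.ndarray, margin: float = 1.05) -> float:
    """``margin * max(train_errors)`` — a value exceeding every training error."""
    train_errors = np.asarray(train_errors, dtype=np.float64)
    if train_errors.size == 0:
        raise ValueError("train_errors must be non-empty")
    if margin < 1.0:
        raise ValueError("margin must be >= 1")
    return float(margin * np.max(train_errors))


def classify(
    model: LSTMAutoencoder,
    threshold: float,
    test: np.ndarray,
    source_frames: Optional[Sequence[int]] = None,
) -> list[ReconstructionResult]:
    """Score scaled test vectors; anomaly iff error strictly exceeds threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    test = np.asarray(test, dtype=np.float64)
    if test.ndim != 2 or test.shape[1] != VECTOR_LEN:
        raise ValueError(f"test must be a (n, {VECTOR_LEN}) array")
    if source_frames is None:
        source_frames = list(range(test.shape[0]))
    if len(source_frames) != test.shape[0]:
        raise ValueError("source_frames misaligned with test vectors")
    errors = model.reconstruction_errors(test)
    return [
        ReconstructionResult(
            error=float(e),
            threshold=float(threshold),
            is_anomaly=bool(e > threshold),
            source_frame=int(sf),
        )
        for e, sf in zip(errors, source_frames)
    ]


def separate(
    results: Sequence[ReconstructionResult], test_vectors: Sequence
) -> tuple[list, list]:
    """Partition test vectors into (anomaly, nonanomaly) sets by the flags."""
    if len(results) != len(test_vectors):
        raise ValueError("results and test_vectors misaligned")
    anomalies, nonanomalies = [], []
    for res, vec in zip(results, test_vectors):
        (anomalies if res.is_anomaly else nonanomalies).append(vec)
    return anomalies, nonanomalies
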