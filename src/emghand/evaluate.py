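"""Evaluation: confusion matrices, the 90-random-movement protocol, servo decoding.

The operational test mirrors the bench protocol of a myoelectric hand: draw
random gestures, run each fresh EMG trial through the complete pipeline
(conditioning chain -> windowing -> feature extraction -> classifier) and
count how many movements the prosthesis would have replicated correctly
("assertiveness").  Classified gestures are decoded into per-finger servo
angle commands.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .acquire import window_trial
from .classifier import MLPModel, predict
from .errors import ParameterError
from .features import FeatureDataset, Standardizer, batch_extract
from .frontend import FrontendConfig, full_chain
from .synth import GESTURES, GestureClass, SynthParams, generate_trial, gesture

__all__ = [
    "ConfusionMatrix",
    "ServoCommand",
    "SERVO_ANGLE_MAP",
    "confusion",
    "accuracy",
    "GesturePipeline",
    "draw_protocol_trials",
    "random_trial_protocol",
    "ProtocolResult",
    "decode",
    "stream",
]

log = logging.getLogger(__name__)

N_CLASSES = 5

# Offset added to the per-session trial indices so protocol trials are fresh
# draws, never duplicates of the training session (indices 0..per_class-1).
PROTOCOL_TRIAL_OFFSET = 100_000


@dataclass
class ConfusionMatrix:
    """5x5 count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES) or np.any(self.counts < 0):
            raise ParameterError("confusion matrix must be 5x5 with non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * np.trace(self.counts) / self.total if self.total else np.nan


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Exact class-by-class counts of true vs predicted labels."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ParameterError("label sequences must have equal length")
    for name, arr in (("true", t), ("predicted", p)):
        if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
            raise ParameterError(f"{name} labels must lie in 0..{N_CLASSES - 1}")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent correct: 100 * trace / total."""
    return cm.accuracy_percent


@dataclass
class GesturePipeline:
    """Trained classifier plus the preprocessing it was fit with."""

    model: MLPModel
    scaler: Standardizer | None = None

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        """Classify a feature matrix (n_features x n_trials)."""
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return predict(self.model, X.T)


def draw_protocol_trials(params: SynthParams, config: FrontendConfig,
                         n: int, seed: int,
                         ) -> tuple[FeatureDataset, np.ndarray]:
    """Generate n fresh random-gesture trials and run them to feature vectors.

    Classes are drawn uniformly; each trial passes through the full
    conditioning chain and windowing before feature extraction.  Deterministic
    for a given (params, seed).
    """
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, N_CLASSES, size=n)
    t0 = time.perf_counter()
    trials = [full_chain(generate_trial(int(c), params,
                                        trial_index=PROTOCOL_TRIAL_OFFSET + i), config)
              for i, c in enumerate(labels)]
    t1 = time.perf_counter()
    windowed = [window_trial(t) for t in trials]
    dataset = batch_extract(windowed)
    log.debug("protocol latency: %.1f ms/trial conditioning, %.1f ms/trial features",
              1e3 * (t1 - t0) / max(n, 1),
              1e3 * (time.perf_counter() - t1) / max(n, 1))
    return dataset, labels


@dataclass
class ProtocolResult:
    """Outcome of the random-movement operational test."""

    n: int
    n_correct: int
    assertiveness_percent: float
    error_percent: float
    confusion: ConfusionMatrix
    labels: np.ndarray
    predictions: np.ndarray


def random_trial_protocol(pipeline: GesturePipeline | Callable[[np.ndarray], np.ndarray],
                          params: SynthParams, config: FrontendConfig,
                          n: int = 90, seed: int = 0) -> ProtocolResult:
    """Score a classifier on n fresh random movements through the full chain.

    ``pipeline`` is either a trained GesturePipeline or any callable mapping a
    (n_features x n_trials) feature matrix to predicted labels.
    """
    dataset, labels = draw_protocol_trials(params, config, n, seed)
    if isinstance(pipeline, GesturePipeline):
        preds = pipeline.predict_features(dataset.X)
    else:
        preds = np.asarray(pipeline(dataset.X), dtype=int)
    cm = confusion(labels, preds)
    n_correct = int(np.trace(cm.counts))
    pct = 100.0 * n_correct / n
    return ProtocolResult(n=n, n_correct=n_correct, assertiveness_percent=pct,
                          error_percent=100.0 - pct, confusion=cm,
                          labels=labels, predictions=preds)


@dataclass(frozen=True)
class ServoCommand:
    """Per-finger servo angles (degrees) for one gesture.

    Channels are (thumb, index, middle, ring, little); 0 deg = extended,
    180 deg = fully flexed.
    """

    angles: tuple[float, float, float, float, float]
    gesture: GestureClass

    def __post_init__(self) -> None:
        if len(self.angles) != 5 or any(not 0.0 <= a <= 180.0 for a in self.angles):
            raise ParameterError("five angles in [0, 180] degrees required")


# Class -> angle map.  Invented calibration (hardware users re-tune it):
# closed hand flexes everything, grip is a power-grasp preshape, the three
# finger gestures flex the named finger only.
SERVO_ANGLE_MAP: dict[int, tuple[float, float, float, float, float]] = {
    0: (180.0, 180.0, 180.0, 180.0, 180.0),  # closed hand
    1: (150.0, 150.0, 150.0, 150.0, 150.0),  # grip
    2: (0.0, 180.0, 0.0, 0.0, 0.0),          # index
    3: (0.0, 0.0, 180.0, 0.0, 0.0),          # middle
    4: (0.0, 0.0, 0.0, 180.0, 0.0),          # ring
}


def decode(label: int | str | GestureClass) -> ServoCommand:
    """Total, deterministic gesture -> servo command map."""
    g = gesture(label)
    return ServoCommand(SERVO_ANGLE_MAP[g.id], g)


def stream(labels: Sequence[int | str | GestureClass],
           dt: float = 0.5) -> list[tuple[float, ServoCommand]]:
    """One timestamped command per classified window, order preserved."""
    return [(i * dt, decode(lab)) for i, lab in enumerate(labels)]
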