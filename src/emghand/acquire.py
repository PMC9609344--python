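"""Acquisition protocol: session accounting, windowing, dataset assembly, splits.

The protocol collects 50 trials per gesture at 1 kHz, keeps the 500-sample
region of interest of each trial (the contraction burst, discarding the
quiescent baseline), and partitions the resulting class-balanced dataset into
train/validation(/test) subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ProtocolError
from .frontend import DigitizedTrial
from .synth import GestureClass

__all__ = [
    "SessionStats",
    "WindowedTrial",
    "session_stats",
    "window_trial",
    "collect_dataset",
    "split_indices",
    "split",
    "write_manifest",
]

WINDOW_POINTS = 500   # samples kept per trial
RMS_FRAME = 25        # moving-RMS frame for burst localization
BYTES_PER_SAMPLE = 2  # serial wire format


@dataclass(frozen=True)
class SessionStats:
    """Exact sample/byte accounting of an acquisition session."""

    duration: float
    rate: float
    n_samples: int
    n_bytes: int


def session_stats(duration: float, rate: float = 1000.0) -> SessionStats:
    """Samples and serialized bytes for a session of the given duration."""
    if duration <= 0:
        raise ParameterError("duration must be positive")
    n = int(round(duration * rate))
    return SessionStats(duration=duration, rate=rate,
                        n_samples=n, n_bytes=BYTES_PER_SAMPLE * n)


@dataclass
class WindowedTrial:
    """The 500-sample region of interest of one trial.

    samples are volts, restored from ADC codes (offset removed) and
    mean-centered; window_bounds index into the source trial (half-open).
    """

    samples: np.ndarray
    label: GestureClass | None
    window_bounds: tuple[int, int]
    no_burst: bool = False
    trial_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)


def _window_energies(x: np.ndarray, length: int) -> np.ndarray:
    """Energy (sum of squares) of every contiguous window of the given length."""
    csq = np.concatenate(([0.0], np.cumsum(x * x)))
    return csq[length:] - csq[:-length]


def window_trial(trial: DigitizedTrial, length: int = WINDOW_POINTS,
                 frame: int = RMS_FRAME,
                 quiescent_energy: float = 1e-18) -> WindowedTrial:
    """Select the contiguous ``length``-sample window of maximal energy.

    Codes are restored to volts (offset reference removed) and mean-centered;
    the window maximizing total energy is kept, ties broken by earliest start
    — equivalent to maximizing the moving-RMS activity over the effort region.
    A quiescent (flat) trial yields the centered window with no_burst=True.
    """
    x = trial.volts()
    n = x.size
    if n < length:
        raise ParameterError(f"trial has {n} samples; windowing needs >= {length}")
    x = x - x.mean()
    energies = _window_energies(x, length)
    emax = energies.max()
    if emax <= quiescent_energy:
        start = (n - length) // 2
        flag = True
    else:
        # earliest window within float tolerance of the maximum (tie policy)
        start = int(np.flatnonzero(energies >= emax * (1.0 - 1e-12))[0])
        flag = False
    return WindowedTrial(
        samples=x[start:start + length] - x[start:start + length].mean(),
        label=trial.label, window_bounds=(start, start + length),
        no_burst=flag, trial_id=trial.trial_id)


def collect_dataset(session: Iterable[DigitizedTrial], per_class: int = 50,
                    length: int = WINDOW_POINTS) -> list[WindowedTrial]:
    """Window a labeled session into a class-balanced, order-stable dataset.

    Takes the first ``per_class`` trials of each gesture (in class-id order,
    preserving within-class input order) and windows each.  A class with
    fewer than ``per_class`` trials raises a protocol error naming it.
    """
    by_class: dict[int, list[DigitizedTrial]] = {}
    names: dict[int, str] = {}
    for t in session:
        if t.label is None:
            raise ProtocolError("session contains an unlabeled trial")
        by_class.setdefault(t.label.id, []).append(t)
        names[t.label.id] = t.label.name
    out: list[WindowedTrial] = []
    for cid in range(5):
        have = by_class.get(cid, [])
        if len(have) < per_class:
            raise ProtocolError(
                f"class {cid} ({names.get(cid, '?')}): {len(have)} trials, "
                f"protocol requires {per_class}")
        out.extend(window_trial(t, length=length) for t in have[:per_class])
    return out


def split_indices(labels: Sequence[int], fractions: Sequence[float],
                  seed: int) -> list[np.ndarray]:
    """Stratified, seeded, disjoint and exhaustive index partition.

    Within each class, indices are shuffled and allocated to the subsets by
    largest-remainder apportionment of the requested fractions, so per-class
    proportions are within one trial of the targets.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size == 0 or np.any(fractions <= 0):
        raise ParameterError("fractions must be positive")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ParameterError(f"fractions must sum to 1, got {fractions.sum()}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[] for _ in fractions]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        quota = fractions * idx.size
        counts = np.floor(quota).astype(int)
        remainder = quota - counts
        for j in np.argsort(-remainder)[: idx.size - counts.sum()]:
            counts[j] += 1
        stops = np.concatenate(([0], np.cumsum(counts)))
        for j in range(fractions.size):
            parts[j].extend(idx[stops[j]:stops[j + 1]])
    out = [np.sort(np.asarray(p, dtype=int)) for p in parts]
    if any(p.size == 0 for p in out):
        raise ParameterError("a requested subset is empty; stratification impossible")
    return out


def split(dataset: Sequence[WindowedTrial], fractions: Sequence[float],
          seed: int) -> tuple[list[WindowedTrial], ...]:
    """Stratified partition of windowed trials (see ``split_indices``)."""
    labels = [t.label.id if t.label is not None else -1 for t in dataset]
    parts = split_indices(labels, fractions, seed)
    return tuple([dataset[i] for i in p] for p in parts)


def write_manifest(dataset: Sequence[WindowedTrial], path: str | Path,
                   files: Sequence[str] | None = None) -> pd.DataFrame:
    """CSV index of a windowed dataset (trial id, class, window bounds)."""
    rows = []
    for i, t in enumerate(dataset):
        rows.append({
            "trial_id": t.trial_id if t.trial_id is not None else f"trial{i:04d}",
            "class": t.label.id if t.label is not None else -1,
            "file": files[i] if files is not None else "",
            "window_start": t.window_bounds[0],
            "window_end": t.window_bounds[1],
            "no_burst": t.no_burst,
        })
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame
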