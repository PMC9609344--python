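"""Hybrid time / frequency / time-frequency EMG feature extraction.

Each 500-sample windowed trial is summarized by an ordered 20-element vector:

====  =======================================================================
pos   feature
====  =======================================================================
1     MAV   mean absolute value, (1/N) sum |x_k|
2     ZC    zero crossings (strict sign alternations, optional deadband)
3     SSC   slope sign changes (strict local extrema, optional deadband)
4     WL    waveform length, sum |x_k - x_{k-1}|
5-7   a1-a3 first three coefficients of an AR(5) model (Burg estimate)
8-9   FFT energy (1/N) sum |X_k|^2  (= sum x^2 by Parseval) and mean power
10-15 STFT over 3 contiguous rectangular windows: energy and mean power each
16-20 v1-v5 variances of the level-1..5 db5 approximation coefficients
====  =======================================================================

Conventions: inputs are mean-centered volts; the AR model is
x(k) = sum_i a_i x(k-i) + e(k); energy is Parseval-normalized so time- and
frequency-domain computations agree exactly; wavelet analysis uses Daubechies
db5 (10 taps) with symmetric boundary extension; variances are sample
variances (N-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pywt
from statsmodels.regression.linear_model import burg as _sm_burg

from .acquire import WindowedTrial
from .errors import ParameterError
from .synth import GestureClass

__all__ = [
    "FEATURE_NAMES",
    "ARModel",
    "FeatureVector",
    "FeatureDataset",
    "Standardizer",
    "mav",
    "zero_crossings",
    "slope_sign_changes",
    "waveform_length",
    "ar_fit",
    "fft_features",
    "stft_features",
    "dwt_variances",
    "extract",
    "batch_extract",
]

FEATURE_NAMES: tuple[str, ...] = (
    "mav", "zc", "ssc", "wl",
    "ar1", "ar2", "ar3",
    "fft_energy", "fft_mean_power",
    "stft1_energy", "stft1_mean_power",
    "stft2_energy", "stft2_mean_power",
    "stft3_energy", "stft3_mean_power",
    "dwt_var1", "dwt_var2", "dwt_var3", "dwt_var4", "dwt_var5",
)

WAVELET = "db5"
DWT_LEVELS = 5
AR_ORDER = 5


def _asarray(x: Sequence[float]) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    if a.ndim != 1:
        raise ParameterError("segment must be one-dimensional")
    if not np.all(np.isfinite(a)):
        raise ParameterError("segment contains non-finite values")
    return a


def mav(x: Sequence[float]) -> float:
    """Mean absolute value (1/N) sum |x_k|."""
    a = _asarray(x)
    if a.size < 1:
        raise ParameterError("MAV needs at least one sample")
    return float(np.mean(np.abs(a)))


def zero_crossings(x: Sequence[float], deadband: float = 0.0) -> int:
    """Count adjacent pairs that cross zero.

    A crossing requires x_k > deadband and x_{k+1} < -deadband or the mirror
    condition; with the default deadband 0 a zero-valued sample breaks both
    strict inequalities and is not counted.
    """
    a = _asarray(x)
    if a.size < 2:
        raise ParameterError("ZC needs at least two samples")
    lo, hi = a[:-1], a[1:]
    eps = deadband
    return int(np.sum(((lo > eps) & (hi < -eps)) | ((lo < -eps) & (hi > eps))))


def slope_sign_changes(x: Sequence[float], deadband: float = 0.0) -> int:
    """Count interior samples strictly above or below both neighbors.

    With a deadband the excursion beyond each neighbor must exceed it.
    """
    a = _asarray(x)
    if a.size < 3:
        raise ParameterError("SSC needs at least three samples")
    prev, cur, nxt = a[:-2], a[1:-1], a[2:]
    eps = deadband
    peaks = (cur - prev > eps) & (cur - nxt > eps)
    troughs = (prev - cur > eps) & (nxt - cur > eps)
    return int(np.sum(peaks | troughs))


def waveform_length(x: Sequence[float]) -> float:
    """Cumulative absolute first difference sum |x_k - x_{k-1}|."""
    a = _asarray(x)
    if a.size < 2:
        raise ParameterError("WL needs at least two samples")
    return float(np.sum(np.abs(np.diff(a))))


@dataclass(frozen=True)
class ARModel:
    """AR(P) fit under the convention x(k) = sum_i a_i x(k-i) + e(k)."""

    order: int
    coeffs: np.ndarray
    sigma2: float
    degenerate: bool = False


def ar_fit(x: Sequence[float], order: int = AR_ORDER) -> ARModel:
    """Burg estimate of an AR(order) model.

    Burg's method minimizes forward+backward prediction error without
    windowing the data, giving stable low-bias estimates on short segments.
    A constant (zero-variance) segment is degenerate: zero coefficients with
    a flagged zero residual variance.
    """
    a = _asarray(x)
    if a.size <= 2 * order:
        raise ParameterError(f"AR({order}) fit needs more than {2 * order} samples")
    if np.ptp(a) == 0.0:
        return ARModel(order, np.zeros(order), 0.0, degenerate=True)
    coeffs, sigma2 = _sm_burg(a, order=order, demean=True)
    return ARModel(order, np.asarray(coeffs, dtype=float), float(sigma2))


def fft_features(x: Sequence[float]) -> tuple[float, float]:
    """(energy, mean power) from the DFT.

    energy = (1/N) sum |X_k|^2, which by Parseval equals sum x_n^2;
    mean power = energy / N.
    """
    a = _asarray(x)
    if a.size < 2:
        raise ParameterError("FFT features need at least two samples")
    spectrum = np.fft.fft(a)
    energy = float(np.sum(np.abs(spectrum) ** 2) / a.size)
    return energy, energy / a.size


def stft_features(x: Sequence[float], n_windows: int = 3) -> tuple[float, ...]:
    """Per-window (energy, mean power) over contiguous rectangular windows.

    The segment is split into ``n_windows`` equal parts (remainder appended to
    the last); each part is Fourier-analyzed exactly as in ``fft_features``.
    Because the rectangular windows partition the segment, the window energies
    sum to the total energy.
    """
    a = _asarray(x)
    if a.size < n_windows:
        raise ParameterError(f"STFT needs at least {n_windows} samples")
    base = a.size // n_windows
    out: list[float] = []
    for w in range(n_windows):
        start = w * base
        stop = a.size if w == n_windows - 1 else start + base
        out.extend(fft_features(a[start:stop]))
    return tuple(out)


def _min_dwt_length(wavelet: str = WAVELET, levels: int = DWT_LEVELS) -> int:
    flen = pywt.Wavelet(wavelet).dec_len
    return (flen - 1) * 2 ** levels


def dwt_variances(x: Sequence[float], wavelet: str = WAVELET,
                  levels: int = DWT_LEVELS, use_details: bool = False,
                  ddof: int = 1) -> np.ndarray:
    """Sample variance of the approximation coefficients at each level 1..5.

    The db5 filter bank is applied recursively (symmetric boundary extension);
    at every level the approximation branch is kept and its variance recorded.
    ``use_details`` switches to the detail-branch variant.
    """
    a = _asarray(x)
    need = _min_dwt_length(wavelet, levels)
    if a.size < need:
        raise ParameterError(
            f"{levels}-level {wavelet} decomposition needs at least {need} samples, "
            f"got {a.size}")
    out = np.empty(levels)
    approx = a
    for j in range(levels):
        approx, detail = pywt.dwt(approx, wavelet, mode="symmetric")
        coeffs = detail if use_details else approx
        out[j] = np.var(coeffs, ddof=ddof)
    return out


@dataclass
class FeatureVector:
    """Ordered 20-element hybrid characteristics vector with its label."""

    values: np.ndarray
    label: GestureClass | None = None
    ar_degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ParameterError(f"feature vector must have {len(FEATURE_NAMES)} elements")


def extract(trial: WindowedTrial | Sequence[float],
            label: GestureClass | None = None,
            zc_deadband: float = 0.0, ssc_deadband: float = 0.0) -> FeatureVector:
    """Compute the full 20-element feature vector of one windowed trial."""
    if isinstance(trial, WindowedTrial):
        x, label = trial.samples, trial.label
    else:
        x = _asarray(trial)
    ar = ar_fit(x)
    energy, power = fft_features(x)
    values = np.concatenate([
        [mav(x), zero_crossings(x, zc_deadband), slope_sign_changes(x, ssc_deadband),
         waveform_length(x)],
        ar.coeffs[:3],
        [energy, power],
        stft_features(x),
        dwt_variances(x),
    ])
    return FeatureVector(values, label=label, ar_degenerate=ar.degenerate)


@dataclass
class FeatureDataset:
    """Feature matrix (n_features x n_trials) with labels, CSV round-trippable."""

    X: np.ndarray
    labels: np.ndarray
    trial_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.shape[0] != len(FEATURE_NAMES):
            raise ParameterError(f"feature matrix must have {len(FEATURE_NAMES)} rows")
        if self.X.shape[1] != self.labels.size:
            raise ParameterError("label count must match the number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X.T, columns=[f"f{i + 1:02d}" for i in range(self.X.shape[0])])
        frame["label"] = self.labels
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureDataset":
        frame = pd.read_csv(path, float_precision="round_trip")
        labels = frame.pop("label").to_numpy(dtype=int)
        return cls(frame.to_numpy(dtype=np.float64).T, labels)


def batch_extract(trials: Sequence[WindowedTrial], **kwargs) -> FeatureDataset:
    """Extract features from every windowed trial into a 20 x N dataset."""
    vectors = [extract(t, **kwargs) for t in trials]
    X = np.column_stack([v.values for v in vectors]) if vectors else np.empty((20, 0))
    labels = np.array([v.label.id if v.label is not None else -1 for v in vectors], dtype=int)
    ids = [t.trial_id if t.trial_id is not None else f"trial{i:04d}"
           for i, t in enumerate(trials)]
    return FeatureDataset(X, labels, ids)


@dataclass
class Standardizer:
    """Per-feature z-scoring, fit on the training split only.

    Sigmoid hidden units saturate on raw feature scales (energies vs counts
    span orders of magnitude), so standardization is applied before training;
    it is toggleable at the pipeline level.
    """

    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean = X.mean(axis=1)
        sd = X.std(axis=1, ddof=0)
        self.scale = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None or self.scale is None:
            raise ParameterError("standardizer has not been fit")
        return (np.asarray(X, dtype=float) - self.mean[:, None]) / self.scale[:, None]

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(mean=np.asarray(d["mean"], dtype=float),
                   scale=np.asarray(d["scale"], dtype=float))
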