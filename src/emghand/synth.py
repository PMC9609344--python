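"""Seeded synthetic surface-EMG trial generator.

Surface EMG recorded with bipolar skin electrodes is a noise-like bipolar
voltage of at most a few millivolts (below 10 mV), with usable energy over
0-500 Hz and its dominant energy between 50 and 150 Hz.  During a gesture the
signal consists of one or more contraction bursts riding on a near-silent
baseline.  This module simulates such trials: a band-limited Gaussian carrier
multiplied by a smooth raised-cosine contraction envelope, with distinct burst
count, peak amplitude and carrier band per gesture class so that the five
classes are statistically separable.  Optional additive contamination — mains
interference and sub-20 Hz baseline wander — can be injected.

The generator makes no claim of physiological (motor-unit level) fidelity; it
reproduces the amplitude and spectral structure the downstream conditioning
and classification chain assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .errors import ParameterError

__all__ = [
    "GestureClass",
    "GESTURES",
    "gesture",
    "BurstSpec",
    "SynthParams",
    "AnalogSignal",
    "generate_trial",
    "generate_session",
    "add_interference",
    "add_baseline_wander",
    "write_trial_csv",
    "read_trial_csv",
    "write_trial_wav",
]

MAX_PEAK_MV = 10.0  # surface EMG stays below 10 mV peak
DOMINANT_BAND = (50.0, 150.0)  # Hz, where most EMG energy lives


@dataclass(frozen=True)
class GestureClass:
    """One of the five hand gestures the prosthesis replicates."""

    id: int
    name: str


GESTURES: tuple[GestureClass, ...] = (
    GestureClass(0, "closed hand"),
    GestureClass(1, "grip"),
    GestureClass(2, "index"),
    GestureClass(3, "middle"),
    GestureClass(4, "ring"),
)

_BY_NAME = {g.name: g for g in GESTURES}


def gesture(ident: int | str | GestureClass) -> GestureClass:
    """Resolve a gesture class from its id, name or itself."""
    if isinstance(ident, GestureClass):
        ident = ident.id
    if isinstance(ident, str):
        try:
            return _BY_NAME[ident]
        except KeyError:
            raise ParameterError(f"unknown gesture name {ident!r}") from None
    if not (isinstance(ident, (int, np.integer)) and 0 <= ident <= 4):
        raise ParameterError(f"gesture id must be an integer in 0..4, got {ident!r}")
    return GESTURES[int(ident)]


@dataclass(frozen=True)
class BurstSpec:
    """Contraction-envelope descriptor for one gesture class.

    onsets/widths are in seconds (raised-cosine bumps), peak_mv is the target
    peak amplitude in millivolts, band is the carrier noise band in Hz.
    """

    onsets: tuple[float, ...]
    widths: tuple[float, ...]
    peak_mv: float
    band: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.onsets) != len(self.widths):
            raise ParameterError("onsets and widths must have equal length")
        if not 0.0 <= self.peak_mv < MAX_PEAK_MV:
            raise ParameterError(f"peak amplitude must be in [0, {MAX_PEAK_MV}) mV")
        lo, hi = self.band
        if not (0.0 < lo < hi <= 500.0):
            raise ParameterError("carrier band must satisfy 0 < low < high <= 500 Hz")


# Per-class envelope and band structure.  The classes differ in burst count,
# peak amplitude and spectral tilt; bands sit inside the 50-150 Hz dominant
# region so the trial PSD peaks there.
CLASS_BURSTS: dict[int, BurstSpec] = {
    0: BurstSpec(onsets=(0.15,), widths=(0.35,), peak_mv=3.0, band=(60.0, 145.0)),
    1: BurstSpec(onsets=(0.12, 0.38), widths=(0.14, 0.14), peak_mv=2.2, band=(55.0, 120.0)),
    2: BurstSpec(onsets=(0.20,), widths=(0.18,), peak_mv=1.3, band=(80.0, 145.0)),
    3: BurstSpec(onsets=(0.15, 0.35), widths=(0.10, 0.10), peak_mv=1.7, band=(70.0, 140.0)),
    4: BurstSpec(onsets=(0.10, 0.25, 0.40), widths=(0.08, 0.08, 0.08), peak_mv=0.9, band=(55.0, 110.0)),
}


@dataclass(frozen=True)
class SynthParams:
    """Generation parameters. ``seed`` is mandatory for reproducibility.

    Amplitudes are in millivolts; rates and frequencies in Hz; durations in
    seconds.  ``amplitude_jitter`` and ``onset_jitter_s`` add per-trial
    variability so repeated trials of one gesture are not identical.
    ``noise_floor_rel`` is baseline muscle tone relative to the burst peak.
    """

    seed: int
    internal_rate: float = 10_000.0
    trial_duration: float = 0.8
    mains_hz: float = 60.0
    mains_amplitude_mv: float = 0.0
    wander_hz: float = 5.0
    wander_amplitude_mv: float = 0.0
    amplitude_jitter: float = 0.15
    onset_jitter_s: float = 0.03
    noise_floor_rel: float = 0.02
    bursts: Mapping[int, BurstSpec] = field(default_factory=lambda: dict(CLASS_BURSTS))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        if self.trial_duration <= 0:
            raise ParameterError("trial_duration must be positive")
        if self.internal_rate <= 2 * 500.0:
            raise ParameterError("internal_rate must exceed twice the 500 Hz band edge")


@dataclass
class AnalogSignal:
    """A continuous-domain voltage trace, simulated at a high internal rate.

    samples are bipolar volts; rate in Hz; meta records provenance.
    """

    samples: np.ndarray
    rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("signal contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate


def _envelope(spec: BurstSpec, n: int, rate: float, rng: np.random.Generator,
              onset_jitter: float, floor: float) -> np.ndarray:
    t = np.arange(n) / rate
    env = np.full(n, floor)
    for onset, width in zip(spec.onsets, spec.widths):
        onset = onset + onset_jitter * rng.uniform(-1.0, 1.0)
        # raised-cosine (Hann) bump of the given width
        rel = (t - onset) / max(width, 1e-9)
        mask = (rel >= 0.0) & (rel <= 1.0)
        env[mask] = np.maximum(env[mask], 0.5 * (1.0 - np.cos(2.0 * np.pi * rel[mask])))
    return env


def _carrier(band: tuple[float, float], n: int, rate: float,
             rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    return sps.sosfilt(sos, white)


def generate_trial(cls: int | str | GestureClass, params: SynthParams,
                   trial_index: int = 0) -> AnalogSignal:
    """Generate one synthetic EMG trial for a gesture class.

    Deterministic for a given (class, params.seed, trial_index).  The trace is
    scaled so its peak equals the class peak amplitude (with per-trial jitter);
    a zero peak amplitude yields an all-zero trace before contamination.
    """
    g = gesture(cls)
    spec = params.bursts[g.id]
    rng = np.random.default_rng([params.seed, g.id, trial_index])
    n = int(round(params.trial_duration * params.internal_rate))

    x = _carrier(spec.band, n, params.internal_rate, rng)
    x *= _envelope(spec, n, params.internal_rate, rng,
                   params.onset_jitter_s, params.noise_floor_rel)

    peak_v = spec.peak_mv * 1e-3 * (1.0 + params.amplitude_jitter * rng.uniform(-1.0, 1.0))
    top = np.max(np.abs(x))
    x = x * (peak_v / top) if top > 0 and peak_v > 0 else np.zeros(n)

    sig = AnalogSignal(x, params.internal_rate,
                       meta={"class_id": g.id, "class_name": g.name,
                             "seed": params.seed, "trial_index": trial_index})
    if params.mains_amplitude_mv > 0:
        sig = add_interference(sig, params.mains_hz, params.mains_amplitude_mv)
    if params.wander_amplitude_mv > 0:
        sig = add_baseline_wander(sig, params.wander_hz, params.wander_amplitude_mv)
    return sig


def generate_session(protocol: Mapping[str, int], params: SynthParams,
                     ) -> list[tuple[AnalogSignal, GestureClass]]:
    """Generate a labeled acquisition session.

    protocol: {"per_class_trials": int, "points": int} where points is the
    digitized (1 kHz) trial length the downstream windowing expects.  Every
    trial is long enough to yield that many 1 kHz samples.
    """
    per_class = int(protocol["per_class_trials"])
    points = int(protocol.get("points", 500))
    if per_class < 1:
        raise ParameterError("per_class_trials must be >= 1")
    needed = points / 1000.0
    if params.trial_duration < needed:
        params = replace(params, trial_duration=needed)
    out: list[tuple[AnalogSignal, GestureClass]] = []
    for g in GESTURES:
        for t in range(per_class):
            out.append((generate_trial(g, params, trial_index=t), g))
    return out


def _add_tone(sig: AnalogSignal, f: float, amp_mv: float, tag: str) -> AnalogSignal:
    if amp_mv == 0:
        return AnalogSignal(sig.samples.copy(), sig.rate, dict(sig.meta))
    tone = amp_mv * 1e-3 * np.sin(2.0 * np.pi * f * sig.times())
    meta = dict(sig.meta)
    meta["contamination"] = list(meta.get("contamination", [])) + [{tag: {"hz": f, "mv": amp_mv}}]
    return AnalogSignal(sig.samples + tone, sig.rate, meta)


def add_interference(sig: AnalogSignal, mains_hz: float, amp_mv: float) -> AnalogSignal:
    """Add a mains-frequency sinusoid (50/60 Hz power-line pickup)."""
    if mains_hz <= 0:
        raise ParameterError("mains frequency must be positive")
    return _add_tone(sig, mains_hz, amp_mv, "mains")


def add_baseline_wander(sig: AnalogSignal, f: float, amp_mv: float) -> AnalogSignal:
    """Add sub-20 Hz baseline wander (electrode-cable motion artifact)."""
    if not 0 < f < 20.0:
        raise ParameterError("wander frequency must lie strictly below 20 Hz")
    return _add_tone(sig, f, amp_mv, "wander")


# ---------------------------------------------------------------------------
# writers

def write_trial_csv(sig: AnalogSignal, path: str | Path) -> None:
    """Single-column CSV of volts with a JSON sidecar (rate + metadata)."""
    path = Path(path)
    np.savetxt(path, sig.samples, fmt="%.9e", header="volts", comments="")
    sidecar = {"rate_hz": sig.rate, **sig.meta}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trial_csv(path: str | Path) -> AnalogSignal:
    path = Path(path)
    samples = np.loadtxt(path, skiprows=1)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta: dict = {}
    rate = 10_000.0
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        rate = float(meta.pop("rate_hz", rate))
    return AnalogSignal(samples, rate, meta)


def write_trial_wav(sig: AnalogSignal, path: str | Path,
                    full_scale_mv: float = MAX_PEAK_MV) -> None:
    """16-bit WAV at the internal rate; full scale maps to ``full_scale_mv``."""
    scaled = np.clip(sig.samples / (full_scale_mv * 1e-3), -1.0, 1.0)
    wavfile.write(str(path), int(sig.rate), (scaled * 32767).astype(np.int16))
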