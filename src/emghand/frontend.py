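"""Digital emulation of the analog EMG conditioning chain.

The chain mirrors a low-cost analog front end: an instrumentation
pre-amplifier, a 3rd-order Butterworth low-pass (design 500 Hz, realized
471 Hz), a 3rd-order Butterworth high-pass (design 20 Hz, realized 22.7 Hz),
a non-inverting final gain stage (range 1-30), a summing-amplifier DC offset
that re-references the bipolar signal for a unipolar ADC, and a 10-bit
0-5 V ADC sampling at 1 kHz.

Filters are realized digitally by bilinear transform of the analog Butterworth
prototype (scipy's design, prewarped at the cutoff) and applied once, causally,
as the real-time analog chain would.  Near the Nyquist rate the bilinear
transform compresses the response relative to the analog magnitude; at the
10 kHz internal rate the emulation is faithful through the EMG band and
beyond, and converges to the analytic |H| everywhere as the rate grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .synth import AnalogSignal, GestureClass

__all__ = [
    "AmplifierSpec",
    "FilterSpec",
    "AdcSpec",
    "DigitizedTrial",
    "FrontendConfig",
    "instrumentation_gain",
    "apply_instrumentation",
    "butterworth3",
    "butterworth_analytic_magnitude",
    "butterworth_realized_magnitude",
    "noninverting_gain",
    "apply_gain",
    "offset_stage",
    "adc_quantize",
    "nyquist_min_rate",
    "full_chain",
]

log = logging.getLogger(__name__)

LP_FC_DESIGN, LP_FC_REALIZED = 500.0, 471.0
HP_FC_DESIGN, HP_FC_REALIZED = 20.0, 22.7
FINAL_GAIN_RANGE = (1.0, 30.0)


@dataclass(frozen=True)
class AmplifierSpec:
    """Resistor network of the two gain stages.

    r1..r4 set the instrumentation (differential) stage; r_fb/r_in set the
    final non-inverting stage.  Defaults reproduce the tuned gains 31 and 21.
    """

    r1: float = 1_000.0
    r2: float = 15_000.0
    r3: float = 10_000.0
    r4: float = 10_000.0
    r_fb: float = 20_000.0
    r_in: float = 1_000.0

    def __post_init__(self) -> None:
        for name in ("r2", "r3", "r4", "r_fb", "r_in"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.r3 <= 0 or self.r_in <= 0:
            raise ParameterError("r3 and r_in must be positive")


def instrumentation_gain(spec: AmplifierSpec) -> float:
    """Differential gain (r4/r3) * (2*r2/r1 + 1) of the instrumentation stage."""
    if spec.r1 <= 0:
        raise ParameterError("r1 must be positive (gain diverges as r1 -> 0)")
    return (spec.r4 / spec.r3) * (2.0 * spec.r2 / spec.r1 + 1.0)


def apply_instrumentation(v1: np.ndarray | float, v2: np.ndarray | float,
                          spec: AmplifierSpec) -> np.ndarray | float:
    """Pre-amplifier output gain * (v2 - v1)."""
    return instrumentation_gain(spec) * (np.asarray(v2) - np.asarray(v1))


def noninverting_gain(r_fb: float, r_in: float) -> float:
    """Gain 1 + r_fb/r_in of the non-inverting final stage."""
    if r_in <= 0:
        raise ParameterError("r_in must be positive")
    if r_fb < 0:
        raise ParameterError("r_fb must be non-negative")
    return 1.0 + r_fb / r_in


def apply_gain(sig: AnalogSignal, gain: float,
               limits: tuple[float, float] | None = FINAL_GAIN_RANGE) -> AnalogSignal:
    """Scale a signal; gains outside the configured range are clamped with a warning."""
    if limits is not None and not (limits[0] <= gain <= limits[1]):
        clamped = float(np.clip(gain, *limits))
        log.warning("requested gain %.3g outside design range %s; clamped to %.3g",
                    gain, limits, clamped)
        gain = clamped
    return AnalogSignal(sig.samples * gain, sig.rate, dict(sig.meta))


@dataclass(frozen=True)
class FilterSpec:
    """3rd-order Butterworth filter (low- or high-pass) at cutoff fc Hz."""

    kind: Literal["lowpass", "highpass"]
    fc: float
    order: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass"):
            raise ParameterError("kind must be 'lowpass' or 'highpass'")
        if self.fc <= 0:
            raise ParameterError("cutoff must be positive")


LOWPASS = FilterSpec("lowpass", LP_FC_REALIZED)
HIGHPASS = FilterSpec("highpass", HP_FC_REALIZED)


def _sos(spec: FilterSpec, rate: float) -> np.ndarray:
    if spec.fc >= rate / 2.0:
        raise ParameterError(
            f"cutoff {spec.fc} Hz must lie below the Nyquist rate {rate / 2.0} Hz")
    return sps.butter(spec.order, spec.fc, btype=spec.kind, fs=rate, output="sos")


def butterworth3(sig: AnalogSignal, spec: FilterSpec) -> AnalogSignal:
    """Apply the filter once, causally (single-pass, as in the analog chain)."""
    y = sps.sosfilt(_sos(spec, sig.rate), sig.samples)
    return AnalogSignal(y, sig.rate, dict(sig.meta))


def butterworth_analytic_magnitude(freqs: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Analytic |H(f)| of the order-n Butterworth prototype.

    Low-pass: 1/sqrt(1 + (f/fc)^(2n)); high-pass mirrors with fc/f.
    """
    f = np.asarray(freqs, dtype=float)
    ratio = f / spec.fc if spec.kind == "lowpass" else spec.fc / np.where(f > 0, f, np.nan)
    return 1.0 / np.sqrt(1.0 + ratio ** (2 * spec.order))


def butterworth_realized_magnitude(freqs: np.ndarray, spec: FilterSpec,
                                   rate: float) -> np.ndarray:
    """|H| of the digital (bilinear) realization at the given sample rate."""
    _, h = sps.sosfreqz(_sos(spec, rate), worN=np.asarray(freqs, dtype=float), fs=rate)
    return np.abs(h)


def offset_stage(sig: AnalogSignal, v_ref: float) -> AnalogSignal:
    """Summing-amplifier DC shift: re-reference the bipolar signal at v_ref."""
    return AnalogSignal(sig.samples + v_ref, sig.rate, dict(sig.meta))


@dataclass(frozen=True)
class AdcSpec:
    """Successive-approximation ADC model: 10-bit, 0-5 V, 1 kHz by default."""

    bits: int = 10
    v_min: float = 0.0
    v_max: float = 5.0
    rate: float = 1000.0
    offset_ref: float = 2.5

    def __post_init__(self) -> None:
        if self.bits < 1 or self.v_max <= self.v_min or self.rate <= 0:
            raise ParameterError("invalid ADC specification")

    @property
    def n_codes(self) -> int:
        return 2 ** self.bits

    @property
    def lsb(self) -> float:
        return (self.v_max - self.v_min) / (self.n_codes - 1)


@dataclass
class DigitizedTrial:
    """One 10-bit digitized gesture recording at the ADC rate."""

    codes: np.ndarray
    rate: float
    label: GestureClass | None = None
    trial_id: str | None = None
    adc: AdcSpec = field(default_factory=AdcSpec)
    n_clipped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)

    def volts(self) -> np.ndarray:
        """Map codes back to input volts, offset reference removed."""
        return self.codes * self.adc.lsb + self.adc.v_min - self.adc.offset_ref


def adc_quantize(sig: AnalogSignal, spec: AdcSpec = AdcSpec()) -> DigitizedTrial:
    """Quantize to the nearest code (round half up), clipping out-of-range values.

    If the signal rate is an integer multiple of the ADC rate it is decimated
    by stride; any anti-alias filtering is the chain's low-pass responsibility.
    """
    x = sig.samples
    if sig.rate != spec.rate:
        factor = sig.rate / spec.rate
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ParameterError(
                f"signal rate {sig.rate} is not an integer multiple of ADC rate {spec.rate}")
        x = x[:: int(round(factor))]
    span = spec.v_max - spec.v_min
    scaled = (x - spec.v_min) / span * (spec.n_codes - 1)
    codes = np.floor(scaled + 0.5)  # round half up
    n_clipped = int(np.sum((codes < 0) | (codes > spec.n_codes - 1)))
    codes = np.clip(codes, 0, spec.n_codes - 1).astype(np.int64)
    label = sig.meta.get("class_id")
    return DigitizedTrial(
        codes=codes, rate=spec.rate,
        label=None if label is None else GestureClass(int(label), str(sig.meta.get("class_name", label))),
        adc=spec, n_clipped=n_clipped, meta=dict(sig.meta))


def nyquist_min_rate(f_signal: float) -> float:
    """Minimum sampling rate (2 * f_signal) that permits reconstruction."""
    if f_signal <= 0:
        raise ParameterError("signal frequency must be positive")
    return 2.0 * f_signal


@dataclass(frozen=True)
class FrontendConfig:
    """Complete conditioning-chain configuration.

    Defaults are the tuned operating point: pre-amplifier gain 31, final gain
    21 (total 651), realized cutoffs 471 / 22.7 Hz, mid-scale 2.5 V offset on
    a 10-bit 0-5 V, 1 kHz ADC.  An alternative 1.5 V offset preset matches a
    hardware tuning that biases the quiescent level below mid-scale.
    """

    preamp_gain: float = 31.0
    final_gain: float = 21.0
    lp_fc: float = LP_FC_REALIZED
    hp_fc: float = HP_FC_REALIZED
    offset_v: float = 2.5
    adc_bits: int = 10
    adc_rate: float = 1000.0
    adc_v_min: float = 0.0
    adc_v_max: float = 5.0

    @property
    def adc(self) -> AdcSpec:
        return AdcSpec(bits=self.adc_bits, v_min=self.adc_v_min, v_max=self.adc_v_max,
                       rate=self.adc_rate, offset_ref=self.offset_v)

    @property
    def total_gain(self) -> float:
        return self.preamp_gain * float(np.clip(self.final_gain, *FINAL_GAIN_RANGE))

    @classmethod
    def from_dict(cls, d: dict) -> "FrontendConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})

    @classmethod
    def from_toml(cls, path: str | Path) -> "FrontendConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def full_chain(sig: AnalogSignal, config: FrontendConfig = FrontendConfig(),
               bypass_highpass: bool = False) -> DigitizedTrial:
    """Run the five conditioning stages in order and digitize.

    pre-amplification -> low-pass -> high-pass -> final gain -> offset -> ADC.
    """
    x = AnalogSignal(sig.samples * config.preamp_gain, sig.rate, dict(sig.meta))
    x = butterworth3(x, FilterSpec("lowpass", config.lp_fc))
    if not bypass_highpass:
        x = butterworth3(x, FilterSpec("highpass", config.hp_fc))
    x = apply_gain(x, config.final_gain)
    x = offset_stage(x, config.offset_v)
    return adc_quantize(x, config.adc)


def write_trial_codes_csv(trial: DigitizedTrial, path: str | Path) -> None:
    """Integer-code CSV with a JSON sidecar (rate, label, clip count)."""
    path = Path(path)
    np.savetxt(path, trial.codes, fmt="%d", header="code", comments="")
    sidecar = {
        "rate_hz": trial.rate,
        "label": None if trial.label is None else trial.label.id,
        "n_clipped": trial.n_clipped,
        "adc_bits": trial.adc.bits,
        "offset_ref_v": trial.adc.offset_ref,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
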