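"""Synthetic PCD pulse trains with controlled cavitation signatures.

Emulates what a passive cavitation detector records during microbubble
sonication: each pulse is a sum of harmonic tones ``n*f`` (volumetric
bubble oscillation), ultraharmonic tones ``(m/2)*f`` (shell oscillation)
and white Gaussian broadband noise (inertial collapse), at amplitudes set
by an :class:`EmissionSpec`.  Component phases are drawn per pulse from a
seeded generator so repeated calls are bit-identical.  An optional
sinusoidal amplitude modulation across pulses emulates the physiological
periodicity of cavitation levels at the breathing rate.

A pressure-ramp builder produces groups of pulses whose component
amplitudes follow simple pressure-response models (linear, saturating
plateau, threshold onset), mirroring a PCD calibration sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .acoustic import PulseRecord
from .errors import ConfigurationError

__all__ = ["EmissionSpec", "generate_pulses", "generate_ramp", "RESPONSE_MODELS"]


@dataclass(frozen=True)
class EmissionSpec:
    """Amplitudes and acquisition layout for a synthetic pulse train.

    ``harmonic_amps`` maps harmonic order n to tone amplitude (volts);
    ``ultraharmonic_amps`` maps odd order m to the amplitude of the tone at
    ``(m/2)*f``.  ``broadband_rms`` is the RMS of the white Gaussian noise
    component.  ``modulation`` is an optional ``(period_s, depth)`` pair
    applying a sinusoidal amplitude envelope across pulses (depth in [0, 1],
    e.g. a 4 s period emulating the breathing rate).
    """

    harmonic_amps: Mapping[int, float] = field(default_factory=dict)
    ultraharmonic_amps: Mapping[int, float] = field(default_factory=dict)
    broadband_rms: float = 0.0
    fundamental_amp: float = 0.0
    noise_seed: int = 0
    pulse_length: float = 10e-3
    n_pulses: int = 1
    pulse_repetition_freq: float = 2.0
    modulation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        amps = list(self.harmonic_amps.values()) + list(self.ultraharmonic_amps.values())
        if any(a < 0 for a in amps) or self.broadband_rms < 0 or self.fundamental_amp < 0:
            raise ConfigurationError("component amplitudes must be >= 0")
        if any(m % 2 == 0 for m in self.ultraharmonic_amps):
            raise ConfigurationError("ultraharmonic orders must be odd")
        if self.pulse_length <= 0 or self.n_pulses < 1:
            raise ConfigurationError("pulse_length must be > 0 and n_pulses >= 1")

    def scaled(self, h: float = 1.0, u: float = 1.0, b: float = 1.0) -> "EmissionSpec":
        """A copy with harmonic/ultraharmonic/broadband amplitudes multiplied."""
        if min(h, u, b) < 0:
            raise ConfigurationError("amplitude multipliers must be >= 0")
        return EmissionSpec(
            harmonic_amps={n: a * h for n, a in self.harmonic_amps.items()},
            ultraharmonic_amps={m: a * u for m, a in self.ultraharmonic_amps.items()},
            broadband_rms=self.broadband_rms * b,
            fundamental_amp=self.fundamental_amp,
            noise_seed=self.noise_seed,
            pulse_length=self.pulse_length,
            n_pulses=self.n_pulses,
            pulse_repetition_freq=self.pulse_repetition_freq,
            modulation=self.modulation,
        )


def generate_pulses(
    spec: EmissionSpec, sample_rate: float = 50e6, excitation_freq: float = 0.5e6
) -> list[PulseRecord]:
    """Render the pulse train described by ``spec``.

    Each pulse is ``sum_n A_n sin(2 pi n f t + phi_n) +
    sum_m A_m sin(2 pi (m/2) f t + phi_m) + noise``, with phases and noise
    drawn from ``numpy``'s PCG64 seeded with ``spec.noise_seed`` -- the
    output is bit-identical for a fixed seed.
    """
    n_samples = round(spec.pulse_length * sample_rate)
    if abs(n_samples - spec.pulse_length * sample_rate) > 1e-6 or n_samples < 1024:
        raise ConfigurationError(
            "pulse_length x sample_rate must be an integer >= 1024 samples"
        )
    rng = np.random.default_rng(spec.noise_seed)
    t = np.arange(n_samples) / sample_rate
    components: list[tuple[float, float]] = [(1.0, spec.fundamental_amp)]
    components += [(float(n), a) for n, a in sorted(spec.harmonic_amps.items())]
    components += [(m / 2.0, a) for m, a in sorted(spec.ultraharmonic_amps.items())]

    pulses = []
    for k in range(spec.n_pulses):
        envelope = 1.0
        if spec.modulation is not None:
            period, depth = spec.modulation
            if period <= 0 or not (0 <= depth <= 1):
                raise ConfigurationError("modulation must be (period > 0, depth in [0, 1])")
            t_pulse = k / spec.pulse_repetition_freq
            envelope = 1.0 + depth * np.sin(2 * np.pi * t_pulse / period)
        x = np.zeros(n_samples)
        for mult, amp in components:
            phase = rng.uniform(0, 2 * np.pi)
            if amp > 0:
                x += envelope * amp * np.sin(2 * np.pi * mult * excitation_freq * t + phase)
        if spec.broadband_rms > 0:
            x += envelope * rng.normal(0.0, spec.broadband_rms, n_samples)
        else:
            rng.normal(0.0, 1.0, n_samples)  # keep the stream position seed-stable
        pulses.append(
            PulseRecord(
                samples=x,
                sample_rate=sample_rate,
                excitation_freq=excitation_freq,
                pulse_index=k,
                timestamp=k / spec.pulse_repetition_freq,
            )
        )
    return pulses


def _linear(p: np.ndarray) -> np.ndarray:
    return p / p.max()


def _plateau(p: np.ndarray) -> np.ndarray:
    # saturating response: rises then flattens at the upper pressures
    half = 0.4 * p.max()
    r = p / (p + half)
    return r / r.max()


def _threshold(p: np.ndarray) -> np.ndarray:
    # onset above ~40% of the top pressure, linear beyond
    onset = 0.4 * p.max()
    r = np.clip(p - onset, 0.0, None)
    return r / r.max() if r.max() > 0 else r


RESPONSE_MODELS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": _linear,
    "plateau": _plateau,
    "threshold": _threshold,
}


def generate_ramp(
    base_spec: EmissionSpec,
    pressures: Sequence[float],
    response_model: Mapping[str, str | Callable[[np.ndarray], np.ndarray]],
    sample_rate: float = 50e6,
    excitation_freq: float = 0.5e6,
) -> dict[float, list[PulseRecord]]:
    """Pulse groups over a monotone pressure sweep.

    ``response_model`` maps each channel (``"harmonic"``, ``"ultraharmonic"``,
    ``"broadband"``) to a built-in model name (``"linear"``, ``"plateau"``,
    ``"threshold"``) or a callable ``pressures -> multipliers``.  Channels
    left out keep the base amplitudes at every step.  Each step gets its own
    deterministic sub-seed derived from ``base_spec.noise_seed``.
    """
    p = np.asarray(list(pressures), dtype=float)
    if p.size == 0:
        raise ConfigurationError("no pressures given")
    if p.size > 1 and np.any(np.diff(p) <= 0):
        raise ConfigurationError("pressures must be strictly increasing")

    multipliers: dict[str, np.ndarray] = {}
    for channel, model in response_model.items():
        if channel not in ("harmonic", "ultraharmonic", "broadband"):
            raise ConfigurationError(f"unknown channel {channel!r}")
        if callable(model):
            multipliers[channel] = np.asarray(model(p), dtype=float)
        elif model in RESPONSE_MODELS:
            multipliers[channel] = RESPONSE_MODELS[model](p)
        else:
            raise ConfigurationError(f"unknown response model {model!r}")

    seeds = np.random.SeedSequence(base_spec.noise_seed).generate_state(p.size)
    out: dict[float, list[PulseRecord]] = {}
    for i, pressure in enumerate(p):
        spec_i = base_spec.scaled(
            h=float(multipliers.get("harmonic", np.ones_like(p))[i]),
            u=float(multipliers.get("ultraharmonic", np.ones_like(p))[i]),
            b=float(multipliers.get("broadband", np.ones_like(p))[i]),
        )
        spec_i = EmissionSpec(
            harmonic_amps=spec_i.harmonic_amps,
            ultraharmonic_amps=spec_i.ultraharmonic_amps,
            broadband_rms=spec_i.broadband_rms,
            fundamental_amp=spec_i.fundamental_amp,
            noise_seed=int(seeds[i] % (2**31)),
            pulse_length=spec_i.pulse_length,
            n_pulses=spec_i.n_pulses,
            pulse_repetition_freq=spec_i.pulse_repetition_freq,
            modulation=spec_i.modulation,
        )
        out[float(pressure)] = generate_pulses(spec_i, sample_rate, excitation_freq)
    return out
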