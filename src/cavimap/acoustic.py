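"""Per-pulse cavitation levels and summed cavitation doses from PCD waveforms.

During microbubble-mediated focused ultrasound, a passive cavitation
detector (PCD) records the acoustic emissions of the oscillating bubbles.
Three spectral signatures are quantified per 10 ms tone-burst pulse, all
within a 1.25-5.00 MHz analysis band for a 0.5 MHz excitation frequency f:

* harmonics ``n*f`` (n = 3..10) -- volumetric bubble oscillation, yielding
  the stable cavitation level with harmonics ``dSCDh``;
* ultraharmonics ``(m/2)*f`` (m = 5, 7, ..., 19) -- shell oscillation,
  yielding ``dSCDu``;
* broadband emission -- inertial bubble collapse, yielding ``dICD`` from
  the spectrum left after notching out the harmonics (360 kHz-wide notches)
  and ultraharmonics (100 kHz-wide notches).

Each level is the root-mean-squared amplitude (volts) of the corresponding
filtered signal.  The harmonic and ultraharmonic filters keep, per order,
the single spectral maximum inside a 20 kHz search band centred on the
nominal frequency; the RMS of that peak set is ``sqrt(sum_k A_k^2) / sqrt(2)``
(the time-domain RMS of a sum of sinusoids with those amplitudes).  The
broadband RMS is evaluated in the frequency domain via Parseval on the
notched one-sided amplitude spectrum.

Cavitation doses (SCDh, SCDu, ICD) are the per-pulse levels summed over the
whole sonication, optionally after subtracting the mean level of a
pre-injection baseline sonication (floored at zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AliasingError, ConfigurationError, InvalidInputError

__all__ = [
    "PulseRecord",
    "BandScheme",
    "Spectrum",
    "CavitationLevels",
    "CavitationDose",
    "pulse_spectrum",
    "cavitation_levels",
    "cavitation_dose",
    "calibration_ramp",
]

MAX_FREQ_RESOLUTION_HZ = 5e3  # so a 20 kHz peak-search band holds >= 4 bins


@dataclass(frozen=True)
class PulseRecord:
    """One PCD pulse: the sampled waveform plus acquisition metadata.

    ``samples`` are hydrophone voltages; ``sample_rate`` in Hz (50 MHz in the
    reference acquisition); ``excitation_freq`` is the transmit frequency f
    (0.5 MHz); ``timestamp`` is the pulse onset in seconds.
    """

    samples: np.ndarray
    sample_rate: float
    excitation_freq: float = 0.5e6
    pulse_index: int = 0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise InvalidInputError("samples must be a 1-D array of length >= 2")
        if self.sample_rate <= 0:
            raise InvalidInputError("sample_rate must be positive")
        if self.excitation_freq <= 0:
            raise InvalidInputError("excitation_freq must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class BandScheme:
    """Spectral band definitions for the harmonic / ultraharmonic / broadband split.

    Defaults follow the reference scheme for f = 0.5 MHz: analysis band
    1.25-5.00 MHz, harmonic orders 3..10, odd ultraharmonic orders 5..19,
    20 kHz peak-search bands, and suppression notches of 360 kHz (harmonic)
    and 100 kHz (ultraharmonic) total width.  All bands are clipped to the
    analysis range.
    """

    analysis_range: tuple[float, float] = (1.25e6, 5.00e6)
    harmonic_orders: tuple[int, ...] = tuple(range(3, 11))
    ultraharmonic_orders: tuple[int, ...] = tuple(range(5, 20, 2))
    peak_search_halfwidth: float = 10e3
    harmonic_suppress_halfwidth: float = 180e3
    ultraharmonic_suppress_halfwidth: float = 50e3

    def __post_init__(self) -> None:
        lo, hi = self.analysis_range
        if not (0 < lo < hi):
            raise ConfigurationError("analysis_range must satisfy 0 < lo < hi")
        if any(w <= 0 for w in (
            self.peak_search_halfwidth,
            self.harmonic_suppress_halfwidth,
            self.ultraharmonic_suppress_halfwidth,
        )):
            raise ConfigurationError("band halfwidths must be positive")
        if any(m % 2 == 0 for m in self.ultraharmonic_orders):
            raise ConfigurationError("ultraharmonic orders must be odd")

    def harmonic_freqs(self, f: float) -> np.ndarray:
        """Harmonic centre frequencies n*f whose search band meets the analysis range."""
        freqs = np.array([n * f for n in self.harmonic_orders], dtype=float)
        return freqs[self._in_range(freqs, self.peak_search_halfwidth)]

    def ultraharmonic_freqs(self, f: float) -> np.ndarray:
        """Ultraharmonic centre frequencies (m/2)*f meeting the analysis range."""
        freqs = np.array([m * f / 2.0 for m in self.ultraharmonic_orders], dtype=float)
        return freqs[self._in_range(freqs, self.peak_search_halfwidth)]

    def _in_range(self, freqs: np.ndarray, halfwidth: float) -> np.ndarray:
        lo, hi = self.analysis_range
        return (freqs + halfwidth >= lo) & (freqs - halfwidth <= hi)


@dataclass(frozen=True)
class Spectrum:
    """One-sided amplitude spectrum restricted to the analysis band (volts per tone)."""

    freqs: np.ndarray
    amps: np.ndarray
    df: float  # bin width, Hz

    def band_slice(self, center: float, halfwidth: float) -> np.ndarray:
        """Boolean mask of bins within ``center +/- halfwidth``.

        A 1 mHz guard absorbs float-representation jitter so bins sitting
        exactly on a band edge classify deterministically.
        """
        return np.abs(self.freqs - center) <= halfwidth + 1e-3

    def rms(self, mask: np.ndarray | None = None) -> float:
        """Time-domain RMS of the signal holding the (masked) spectral content.

        For a one-sided amplitude spectrum, each retained tone of amplitude A
        contributes A^2/2 to the mean square (Parseval).
        """
        amps = self.amps if mask is None else self.amps[mask]
        return float(np.sqrt(np.sum(amps**2) / 2.0))


@dataclass(frozen=True)
class CavitationLevels:
    """Per-pulse cavitation levels, all RMS voltages and >= 0."""

    dSCDh: float
    dSCDu: float
    dICD: float
    pulse_index: int = 0

    def __post_init__(self) -> None:
        for name in ("dSCDh", "dSCDu", "dICD"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidInputError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class CavitationDose:
    """Summed cavitation doses over one sonication (volt x pulses)."""

    SCDh: float
    SCDu: float
    ICD: float
    n_pulses: int
    baseline_subtracted: bool = False

    @property
    def total(self) -> float:
        return self.SCDh + self.SCDu + self.ICD


def pulse_spectrum(pulse: PulseRecord, scheme: BandScheme | None = None) -> Spectrum:
    """One-sided amplitude spectrum of a pulse, restricted to the analysis band.

    A rectangular window over the full pulse is used, so a tone at an exact
    bin frequency appears as a single bin of amplitude equal to the tone's
    amplitude.  Raises :class:`AliasingError` if the Nyquist frequency lies
    below the top of the analysis band and :class:`InvalidInputError` on
    non-finite samples or a frequency resolution coarser than 5 kHz.
    """
    scheme = scheme or BandScheme()
    x = pulse.samples
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("waveform contains NaN or infinite samples")
    lo, hi = scheme.analysis_range
    nyquist = pulse.sample_rate / 2.0
    if nyquist < hi:
        raise AliasingError(
            f"Nyquist {nyquist:.3g} Hz below analysis-band top {hi:.3g} Hz"
        )
    n = x.size
    df = pulse.sample_rate / n
    if df > MAX_FREQ_RESOLUTION_HZ:
        raise InvalidInputError(
            f"frequency resolution {df:.3g} Hz exceeds {MAX_FREQ_RESOLUTION_HZ:.0f} Hz; "
            "pulse too short for the band scheme"
        )
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / pulse.sample_rate)
    amps = (2.0 / n) * np.abs(spec)
    keep = (freqs >= lo - 1e-3) & (freqs <= hi + 1e-3)  # guard exact band edges
    return Spectrum(freqs=freqs[keep], amps=amps[keep], df=df)


def _peak_set_rms(spec: Spectrum, centers: np.ndarray, halfwidth: float) -> float:
    """RMS of the per-order band maxima: sqrt(sum of peak amplitudes^2)/sqrt(2)."""
    peaks = []
    for c in centers:
        mask = spec.band_slice(c, halfwidth)
        if np.any(mask):
            peaks.append(float(np.max(spec.amps[mask])))
    if not peaks:
        return 0.0
    return float(np.sqrt(np.sum(np.square(peaks)) / 2.0))


def cavitation_levels(pulse: PulseRecord, scheme: BandScheme | None = None) -> CavitationLevels:
    """Harmonic, ultraharmonic and broadband RMS levels of one pulse.

    All three levels are derived from the same amplitude spectrum:
    ``dSCDh``/``dSCDu`` from the per-order 20 kHz-band maxima, ``dICD`` from
    the spectrum after zeroing the harmonic and ultraharmonic notches.
    """
    scheme = scheme or BandScheme()
    spec = pulse_spectrum(pulse, scheme)
    f = pulse.excitation_freq
    h_freqs = scheme.harmonic_freqs(f)
    u_freqs = scheme.ultraharmonic_freqs(f)

    d_scdh = _peak_set_rms(spec, h_freqs, scheme.peak_search_halfwidth)
    d_scdu = _peak_set_rms(spec, u_freqs, scheme.peak_search_halfwidth)

    notch = np.zeros(spec.freqs.size, dtype=bool)
    for c in h_freqs:
        notch |= spec.band_slice(c, scheme.harmonic_suppress_halfwidth)
    for c in u_freqs:
        notch |= spec.band_slice(c, scheme.ultraharmonic_suppress_halfwidth)
    d_icd = spec.rms(~notch)

    return CavitationLevels(
        dSCDh=d_scdh, dSCDu=d_scdu, dICD=d_icd, pulse_index=pulse.pulse_index
    )


def _level_arrays(levels: Sequence[CavitationLevels]) -> np.ndarray:
    return np.array([[lv.dSCDh, lv.dSCDu, lv.dICD] for lv in levels], dtype=float)


def cavitation_dose(
    levels: Sequence[CavitationLevels],
    baseline: Sequence[CavitationLevels] | None = None,
) -> CavitationDose:
    """Sum per-pulse levels into whole-sonication doses.

    If a pre-injection ``baseline`` is supplied, its mean per-pulse level is
    subtracted from every pulse (per channel) before summation, floored at
    zero -- negative cavitation is non-physical.
    """
    if len(levels) == 0:
        raise InvalidInputError("empty pulse sequence")
    arr = _level_arrays(levels)
    if baseline is not None:
        if len(baseline) == 0:
            raise InvalidInputError("baseline supplied but empty")
        arr = np.clip(arr - _level_arrays(baseline).mean(axis=0), 0.0, None)
    sums = arr.sum(axis=0)
    return CavitationDose(
        SCDh=float(sums[0]),
        SCDu=float(sums[1]),
        ICD=float(sums[2]),
        n_pulses=len(levels),
        baseline_subtracted=baseline is not None,
    )


def calibration_ramp(
    pulses_by_pressure: Mapping[float, Iterable[PulseRecord]],
    scheme: BandScheme | None = None,
) -> pd.DataFrame:
    """Per-pressure mean +/- SD of each cavitation level for a pressure ramp.

    Emulates the PCD calibration protocol: consecutive short sonications at
    monotonically increasing pressures (e.g. 100-600 kPa, 10 pulses per
    step).  Returns a DataFrame indexed by ascending pressure with columns
    ``{dSCDh,dSCDu,dICD}_{mean,sd}`` and ``n_pulses``.  Population SD
    (ddof=0); a single-pulse step reports SD 0 with a warning.
    """
    scheme = scheme or BandScheme()
    pressures = list(pulses_by_pressure.keys())
    if len(pressures) == 0:
        raise InvalidInputError("no pressure steps")
    if any(pressures[i] >= pressures[i + 1] for i in range(len(pressures) - 1)):
        warnings.warn("pressure steps not strictly increasing; reordering", stacklevel=2)
    rows = []
    for p in sorted(pressures):
        step = list(pulses_by_pressure[p])
        if len(step) == 0:
            raise InvalidInputError(f"pressure step {p} has no pulses")
        if len(step) == 1:
            warnings.warn(
                f"pressure step {p} has a single pulse; SD reported as 0", stacklevel=2
            )
        arr = _level_arrays([cavitation_levels(pu, scheme) for pu in step])
        rows.append(
            {
                "pressure": float(p),
                "n_pulses": len(step),
                "dSCDh_mean": arr[:, 0].mean(),
                "dSCDh_sd": arr[:, 0].std(ddof=0),
                "dSCDu_mean": arr[:, 1].mean(),
                "dSCDu_sd": arr[:, 1].std(ddof=0),
                "dICD_mean": arr[:, 2].mean(),
                "dICD_sd": arr[:, 2].std(ddof=0),
            }
        )
    return pd.DataFrame(rows).set_index("pressure")
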