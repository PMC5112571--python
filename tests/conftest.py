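"""Shared fixtures: compact acquisition settings for fast spectral tests.

The toy acquisition keeps the default 1.25-5.00 MHz analysis band valid
(Nyquist 6.4 MHz) while using 4096-sample pulses (bin width 3.125 kHz,
finer than the 5 kHz resolution bound), so brute-force spectral oracles
stay cheap.
"""

import numpy as np
import pytest

from cavimap.acoustic import BandScheme, PulseRecord

TOY_FS = 12.8e6
TOY_N = 4096
F0 = 0.5e6


@pytest.fixture(scope="session")
def scheme() -> BandScheme:
    return BandScheme()


def make_tone_pulse(
    components,
    fs: float = TOY_FS,
    n: int = TOY_N,
    phases=None,
    noise_rms: float = 0.0,
    seed: int = 0,
    pulse_index: int = 0,
) -> PulseRecord:
    """Pulse from (frequency, amplitude) pairs at exact FFT bin frequencies.

    Frequencies are snapped to the nearest bin so amplitudes survive the
    rectangular window exactly.
    """
    t = np.arange(n) / fs
    df = fs / n
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    for i, (f, a) in enumerate(components):
        f_snap = round(f / df) * df
        ph = 0.0 if phases is None else phases[i]
        x += a * np.sin(2 * np.pi * f_snap * t + ph)
    if noise_rms > 0:
        x += rng.normal(0.0, noise_rms, n)
    return PulseRecord(samples=x, sample_rate=fs, excitation_freq=F0, pulse_index=pulse_index)


@pytest.fixture()
def tone_pulse():
    return make_tone_pulse
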