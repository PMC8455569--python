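import numpy as np
import pytest

from ecgfusion.synthetic import NoiseSpec, generate_record


@pytest.fixture(scope="session")
def clean60():
    """Noise-free 60-beat record at 360 Hz, 75 bpm."""
    return generate_record(60, 360.0, 0.8, 0.0)


@pytest.fixture(scope="session")
def noisy60():
    """60-beat record with 0.05 mV white noise (fixed seed)."""
    return generate_record(60, 360.0, 0.8, 0.0,
                           noise=NoiseSpec(white_noise_sd=0.05, seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def smooth_signals(n, count, seed, cmax=2.0, fmax=2.0, smin=0.5, smax=1.5):
    """Random time-frequency-concentrated test signals.

    Sums of a few Gaussian envelopes with random centers (|c| <= cmax),
    widths and modulation frequencies (|f| <= fmax), all well inside the
    dimensionless window [-sqrt(n)/2, sqrt(n)/2] — the class of signals a
    finite FrFT discretization represents faithfully.
    """
    r = np.random.default_rng(seed)
    t = (np.arange(n) - n // 2) / np.sqrt(n)
    out = []
    for _ in range(count):
        x = np.zeros(n, dtype=complex)
        for _ in range(r.integers(2, 5)):
            c = r.uniform(-cmax, cmax)
            s = r.uniform(smin, smax)
            f = r.uniform(-fmax, fmax)
            amp = r.uniform(0.5, 1.5) * np.exp(2j * np.pi * r.uniform())
            x += amp * np.exp(-((t - c) ** 2) / (2 * s ** 2)) * np.exp(2j * np.pi * f * t)
        out.append(x)
    return out
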