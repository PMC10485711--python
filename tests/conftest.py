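import numpy as np
import pytest

import hrvgame as hg


@pytest.fixture
def constant_rr() -> hg.RRSeries:
    """60 beats of exactly 1000 ms (60 bpm, zero variability)."""
    return hg.RRSeries(np.full(60, 1000.0))


@pytest.fixture
def calibration() -> hg.Calibration:
    return hg.Calibration(baseline_ihr=60.0, half_range=10.0)


@pytest.fixture
def flat_track(calibration) -> hg.Track:
    """A 60 s track whose target sits at the screen centre in every column."""
    curve = hg.ReferenceCurve(np.full(60, 60.0))
    return hg.build_track(curve, calibration)


def make_rsa_series(
    freq: float,
    amplitude: float = 50.0,
    mean_rr: float = 1000.0,
    duration: float = 300.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> hg.RRSeries:
    """Noise-free (by default) sinusoidally modulated RR series."""
    return hg.generate_rr(
        hg.SimConfig(mean_rr=mean_rr, noise_sd=noise_sd, duration=duration, seed=seed),
        hg.BreathingPattern(freq=freq, amplitude=amplitude),
    )


def random_rr_series(rng: np.random.Generator, n: int) -> hg.RRSeries:
    """A plausible random RR series of n beats (no structure)."""
    return hg.RRSeries(rng.uniform(500.0, 1200.0, size=n))
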