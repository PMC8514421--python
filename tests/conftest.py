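import numpy as np
import pytest

from trapjaw.simulate import StrikeSimConfig, simulate_strike

# the study's mean strike: ~172 deg gape closed in 12 ms by a 0.46 mm chelicera
MEAN_GAPE_DEG = 172.4
MEAN_DURATION_S = 0.012
MEAN_LENGTH_MM = 0.46


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, drift-free strike at the study's mean parameters, 10 kHz."""
    cfg = StrikeSimConfig(
        gape_deg=MEAN_GAPE_DEG,
        duration_s=MEAN_DURATION_S,
        cheliceral_length_mm=MEAN_LENGTH_MM,
        fps=10_000.0,
        noise_px=0.0,
        seed=7,
    )
    return simulate_strike(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Same strike with the default half-pixel digitization noise."""
    cfg = StrikeSimConfig(
        gape_deg=MEAN_GAPE_DEG,
        duration_s=MEAN_DURATION_S,
        cheliceral_length_mm=MEAN_LENGTH_MM,
        fps=10_000.0,
        noise_px=0.5,
        seed=7,
    )
    return simulate_strike(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
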