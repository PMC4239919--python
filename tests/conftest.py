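import numpy as np
import pytest

from sleeponset import SimulationConfig, segment_epochs, synthesize_recording
from sleeponset.synth import BAND_CENTER_HZ, LEVELS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def alpha_only_config():
    """Noise-free config whose only oscillator is the alpha-band one."""
    cfg = SimulationConfig(duration_s=10.0, noise_std=0.0, seed=7)
    table = {lvl: {b: (0.0, 0.0) for b in BAND_CENTER_HZ} for lvl in LEVELS}
    table[6]["alpha"] = (10.0, 10.0)
    cfg.band_amplitude_table = table
    return cfg


@pytest.fixture
def alpha_only_epoch(alpha_only_config):
    rec = synthesize_recording(np.array([6]), alpha_only_config)
    return segment_epochs(rec)[0]


@pytest.fixture(scope="session")
def trend_recording():
    """100 epochs per level in a fixed block layout, default amplitude trends."""
    states = np.repeat(list(LEVELS), 100)
    cfg = SimulationConfig(duration_s=len(states) * 10.0, seed=42)
    return synthesize_recording(states, cfg)
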