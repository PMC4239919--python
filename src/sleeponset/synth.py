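"""Synthetic labeled EEG + respiration recordings with drowsiness-dependent structure.

The generator emulates the band-level trends that make sleep-onset detectable
from scalp EEG: as vigilance declines from awake (level 6) through drowsiness
(5, 4) into sleep (3, 2, 1), alpha activity first rises, beta activity falls,
and delta activity grows strongly in the sleep stages, while breathing becomes
less regular.  Each epoch's EEG is a sum of four band-limited oscillators
(sinusoids at the band midpoints 2, 6, 10.5 and 16.5 Hz, random phase per
epoch) whose amplitudes are looked up per vigilance level, on top of a
white + 1/f Gaussian background.  Respiration is a sinusoid whose phase
accumulates per-cycle jitter that grows as vigilance declines.

The level sequence itself follows a first-order Markov chain over the six
levels, so labeled recordings of any length can be produced reproducibly from
a seed.  None of this claims physiological fidelity — it provides a ground
truth with the right statistical ordering so that every downstream stage
(filtering, wavelet band powers, feature ranking, classification) can be
exercised and checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError
from .signal_io import Recording

LEVELS = (6, 5, 4, 3, 2, 1)  # 6 = awake ... 1 = deep sleep

#: band oscillator center frequencies (Hz): midpoints of delta/theta/alpha/beta
BAND_CENTER_HZ = {"delta": 2.0, "theta": 6.0, "alpha": 10.5, "beta": 16.5}

# Per-level oscillator amplitudes (µV) per band and EEG channel, keyed
# level -> band -> (eeg1, eeg2).  Encodes the qualitative trends: alpha rises
# into drowsiness, beta falls monotonically, delta grows in the sleep levels,
# theta marks early drowsiness.  The parieto-occipital channel (eeg2) carries
# the trends slightly more strongly, as it does in real recordings.
DEFAULT_BAND_AMPLITUDES: dict[int, dict[str, tuple[float, float]]] = {
    6: {"delta": (8.0, 8.0), "theta": (6.0, 6.0), "alpha": (8.0, 9.0), "beta": (10.0, 11.0)},
    5: {"delta": (9.0, 9.5), "theta": (8.0, 8.5), "alpha": (10.0, 11.5), "beta": (8.0, 8.5)},
    4: {"delta": (10.0, 11.0), "theta": (10.0, 11.0), "alpha": (13.0, 15.0), "beta": (6.0, 6.0)},
    3: {"delta": (14.0, 15.5), "theta": (11.0, 12.0), "alpha": (11.0, 12.0), "beta": (5.0, 5.0)},
    2: {"delta": (18.0, 20.0), "theta": (11.5, 12.5), "alpha": (9.0, 10.0), "beta": (4.0, 4.0)},
    1: {"delta": (22.0, 24.0), "theta": (12.0, 13.0), "alpha": (8.0, 8.5), "beta": (3.0, 3.0)},
}

#: per-level std of the per-cycle respiration phase jitter (radians)
DEFAULT_RESP_JITTER = {6: 0.05, 5: 0.10, 4: 0.20, 3: 0.35, 2: 0.50, 1: 0.70}


def _default_transition_matrix(persist: float = 0.8) -> np.ndarray:
    """Nearest-neighbour random walk over the six levels with self-persistence."""
    n = len(LEVELS)
    m = np.zeros((n, n))
    for i in range(n):
        neighbours = [j for j in (i - 1, i + 1) if 0 <= j < n]
        m[i, i] = persist
        for j in neighbours:
            m[i, j] = (1.0 - persist) / len(neighbours)
    return m


@dataclass
class SimulationConfig:
    """Everything needed to generate one labeled synthetic recording."""

    duration_s: float = 600.0
    eeg_rate: float = 100.0
    resp_rate: float = 1.0
    epoch_s: float = 10.0
    transition_matrix: np.ndarray = field(default_factory=_default_transition_matrix)
    band_amplitude_table: dict[int, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BAND_AMPLITUDES.items()}
    )
    resp_base_period_s: float = 4.0
    resp_jitter_by_level: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_RESP_JITTER))
    noise_std: float = 3.0
    start_level: int = 6
    seed: int = 0

    def validate(self) -> None:
        m = np.asarray(self.transition_matrix, dtype=float)
        if m.shape != (6, 6):
            raise ConfigurationError("transition_matrix must be 6x6")
        if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigurationError("transition_matrix rows must be non-negative and sum to 1")
        if self.eeg_rate <= 0 or self.resp_rate <= 0 or self.epoch_s <= 0:
            raise ConfigurationError("rates and epoch length must be positive")
        if abs(self.epoch_s * self.eeg_rate - round(self.epoch_s * self.eeg_rate)) > 1e-9:
            raise ConfigurationError("epoch_s * eeg_rate must be an integer sample count")
        if self.start_level not in LEVELS:
            raise ConfigurationError(f"start_level must be one of {LEVELS}")

    @property
    def n_epochs(self) -> int:
        return int(math.floor(self.duration_s / self.epoch_s))


def generate_state_sequence(config: SimulationConfig) -> np.ndarray:
    """Markov-chain vigilance level per epoch (levels 6..1), reproducible from the seed."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    m = np.asarray(config.transition_matrix, dtype=float)
    idx = LEVELS.index(config.start_level)
    seq = np.empty(config.n_epochs, dtype=int)
    for k in range(config.n_epochs):
        seq[k] = LEVELS[idx]
        idx = rng.choice(6, p=m[idx])
    return seq


def _one_over_f_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance Gaussian noise with ~1/f amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    np.divide(1.0, np.sqrt(f, where=f > 0, out=np.ones_like(f)), where=f > 0, out=scale)
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_recording(states: np.ndarray, config: SimulationConfig) -> Recording:
    """Render a labeled :class:`Recording` for a given vigilance-level sequence.

    EEG epochs are sums of the four band oscillators with level-dependent
    amplitudes plus noise (white and 1/f, equal variance split); respiration
    is a jittered sinusoid whose phase noise grows with drowsiness.
    """
    config.validate()
    states = np.asarray(states, dtype=int)
    if len(states) == 0:
        raise ValidationError("empty state sequence")
    if not np.all(np.isin(states, LEVELS)):
        raise ValidationError("states must lie in levels 6..1")

    rng = np.random.default_rng([config.seed, 1])
    eeg_per_epoch = int(round(config.epoch_s * config.eeg_rate))
    n_eeg = len(states) * eeg_per_epoch
    t_epoch = np.arange(eeg_per_epoch) / config.eeg_rate

    channels = []
    for ch in range(2):
        sig = np.empty(n_eeg)
        for k, level in enumerate(states):
            amps = config.band_amplitude_table[int(level)]
            epoch = np.zeros(eeg_per_epoch)
            for band, fc in BAND_CENTER_HZ.items():
                amp = amps[band][ch]
                if amp != 0.0:
                    phase = rng.uniform(0.0, 2.0 * np.pi)
                    epoch += amp * np.sin(2.0 * np.pi * fc * t_epoch + phase)
            sig[k * eeg_per_epoch : (k + 1) * eeg_per_epoch] = epoch
        if config.noise_std > 0:
            per = config.noise_std / np.sqrt(2.0)
            sig = sig + per * rng.standard_normal(n_eeg) + per * _one_over_f_noise(rng, n_eeg)
        channels.append(sig)

    # respiration: continuous phase with level-dependent per-cycle jitter
    resp_per_epoch = int(round(config.epoch_s * config.resp_rate))
    n_resp = len(states) * resp_per_epoch
    dt = 1.0 / config.resp_rate
    omega = 2.0 * np.pi / config.resp_base_period_s
    cycles_per_sample = dt / config.resp_base_period_s
    phase = rng.uniform(0.0, 2.0 * np.pi)
    resp = np.empty(n_resp)
    for i in range(n_resp):
        level = int(states[min(i // resp_per_epoch, len(states) - 1)])
        jitter_sd = config.resp_jitter_by_level[level]
        phase += omega * dt + rng.normal(0.0, jitter_sd * np.sqrt(cycles_per_sample))
        resp[i] = np.sin(phase)

    return Recording(
        eeg1=channels[0],
        eeg2=channels[1],
        resp=resp,
        eeg_rate=config.eeg_rate,
        resp_rate=config.resp_rate,
        epoch_s=config.epoch_s,
        labels=states.copy(),
    )


def simulate(config: SimulationConfig) -> Recording:
    """Convenience wrapper: draw the level sequence, then render the recording."""
    return synthesize_recording(generate_state_sequence(config), config)
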