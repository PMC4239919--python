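"""Butterworth band-pass preprocessing of raw EEG.

The EEG channels are band-passed to 0.1-40 Hz before any feature is computed;
the respiration channel is deliberately left untouched (its information lives
in the breathing periodicity, which filtering would only distort).  The filter
is a 4th-order Butterworth applied forward-backward (zero phase) by default so
that band-power features are not smeared in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design: pass band ``[low_hz, high_hz]``, Butterworth ``order``."""

    low_hz: float = 0.1
    high_hz: float = 40.0
    order: int = 4
    zero_phase: bool = True


def butter_sos(spec: FilterSpec, rate: float):
    """Second-order-section coefficients for ``spec`` at sampling ``rate``."""
    nyq = rate / 2.0
    if not (0.0 < spec.low_hz < spec.high_hz):
        raise ConfigurationError(f"require 0 < low_hz < high_hz, got {spec.low_hz}, {spec.high_hz}")
    if spec.high_hz >= nyq:
        raise ConfigurationError(f"high_hz {spec.high_hz} must be below Nyquist {nyq}")
    if spec.order < 1:
        raise ConfigurationError("filter order must be >= 1")
    return sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=rate, output="sos")


def bandpass(x: np.ndarray, rate: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Band-pass filter a sample vector, preserving its length.

    With ``zero_phase`` the filter runs forward and backward (squared
    magnitude response, zero group delay); otherwise a single causal pass is
    applied.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("signal must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite samples")
    if len(x) <= 3 * spec.order:
        raise ValidationError(f"signal too short ({len(x)} samples) for order-{spec.order} filter")
    sos = butter_sos(spec, rate)
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def analytic_bandpass_magnitude(f: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Closed-form magnitude of the analog Butterworth band-pass prototype.

    The band-pass is the low-pass prototype ``|H|^2 = 1 / (1 + w^(2n))``
    evaluated at the band-pass frequency variable
    ``w = (f^2 - f_lo*f_hi) / (f * (f_hi - f_lo))``; used as an independent
    check of the implemented response (single pass).
    """
    f = np.asarray(f, dtype=float)
    bw = spec.high_hz - spec.low_hz
    f0sq = spec.low_hz * spec.high_hz
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (f * f - f0sq) / (f * bw)
        mag = 1.0 / np.sqrt(1.0 + w ** (2 * spec.order))
    return np.where(f == 0.0, 0.0, mag)
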