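"""Haar wavelet-packet decomposition and EEG band-power summaries.

A level-``j`` wavelet-packet transform splits a signal into ``2**j`` equal-width
sub-bands.  With the orthonormal Haar filters the transform of a dyadic-length
segment is exact (no boundary handling) and energy preserving.  The natural
(Paley) order of the packet tree is *not* monotone in frequency: every
high-pass branch mirrors the spectrum, so leaves are reordered by the binary
Gray code before band grouping.

At level 6 with a 100 Hz sampling rate each of the 64 leaves covers
``100 / 2**7 = 0.78125`` Hz.  The four conventional EEG bands are mapped onto
contiguous runs of frequency-ordered leaves:

====== ============== ===============
band   leaves (1-based)  nominal range
====== ============== ===============
delta  1-5            0-4 Hz
theta  6-10           4-8 Hz
alpha  11-17          8-13 Hz
beta   18-45          13-20 Hz (nominal; leaf span 13.3-35.2 Hz)
====== ============== ===============

Leaves 46-64 (~35-50 Hz) belong to no band and are excluded from the band
power totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError

#: canonical band order used throughout the package
BANDS = ("delta", "theta", "alpha", "beta")

#: 1-based inclusive ranges of frequency-ordered level-6 leaves per band
BAND_LEAVES: dict[str, tuple[int, int]] = {
    "delta": (1, 5),
    "theta": (6, 10),
    "alpha": (11, 17),
    "beta": (18, 45),
}

DEFAULT_LEVEL = 6
DEFAULT_FS = 100.0


@dataclass
class WaveletPacketLeaves:
    """Frequency-ordered leaf coefficients of one wavelet-packet decomposition.

    ``leaves[m - 1]`` holds the coefficient vector of leaf ``m`` (1-based),
    whose frequency support is ``band_frequency_range(m, level_j, fs)``.
    """

    level_j: int
    fs: float
    leaves: list[np.ndarray] = field(repr=False)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def n_per_leaf(self) -> int:
        return len(self.leaves[0])

    def leaf_energies(self) -> np.ndarray:
        """Sum of squared coefficients per leaf, in frequency order."""
        return np.array([float(np.sum(d * d)) for d in self.leaves])


@dataclass
class BandPowerSummary:
    """Band energies, their total, and the relative (normalised) powers."""

    pwr: dict[str, float]
    pwr_total: float
    relpwr: dict[str, float]
    band_map: dict[str, tuple[int, int]]


def _gray(n: int) -> int:
    return n ^ (n >> 1)


def haar_wpt(segment: np.ndarray, level: int = DEFAULT_LEVEL, fs: float = DEFAULT_FS) -> WaveletPacketLeaves:
    """Full Haar wavelet-packet decomposition of ``segment`` to ``level``.

    Parameters
    ----------
    segment
        Sample vector whose length is divisible by ``2**level``
        (the canonical analysis segment is 128 samples at level 6).
    level
        Decomposition depth; ``2**level`` leaves are produced.
    fs
        Sampling rate in Hz, attached to the result for frequency bookkeeping.

    Returns
    -------
    WaveletPacketLeaves
        ``2**level`` coefficient vectors in frequency (sequency) order.

    Notes
    -----
    One analysis step maps pairs ``(x[2k], x[2k+1])`` to the orthonormal
    low/high outputs ``(x[2k] + x[2k+1]) / sqrt(2)`` and
    ``(x[2k] - x[2k+1]) / sqrt(2)``; the step is applied recursively to both
    outputs.  Natural tree order is converted to frequency order by the Gray
    code permutation: the leaf at natural position ``n`` has frequency
    position ``n ^ (n >> 1)``.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1:
        raise ValidationError("segment must be one-dimensional")
    n_leaves = 2**level
    if len(x) == 0 or len(x) % n_leaves != 0:
        raise ValidationError(
            f"segment length {len(x)} is not a positive multiple of 2**{level} = {n_leaves}"
        )
    if not np.all(np.isfinite(x)):
        raise ValidationError("segment contains non-finite samples")

    nodes = [x]
    for _ in range(level):
        nxt = []
        for node in nodes:
            lo = (node[0::2] + node[1::2]) / np.sqrt(2.0)
            hi = (node[0::2] - node[1::2]) / np.sqrt(2.0)
            nxt.extend((lo, hi))
        nodes = nxt

    # frequency position f holds the node at natural (Paley) position gray(f):
    # every high-pass branch mirrors the spectrum of its children
    leaves = [nodes[_gray(f)] for f in range(n_leaves)]
    return WaveletPacketLeaves(level_j=level, fs=float(fs), leaves=leaves)


def inverse_haar_wpt(leaves: WaveletPacketLeaves) -> np.ndarray:
    """Reconstruct the original segment from frequency-ordered leaves."""
    n_leaves = 2**leaves.level_j
    nodes: list[np.ndarray] = [None] * n_leaves  # type: ignore[list-item]
    for f in range(n_leaves):
        nodes[_gray(f)] = leaves.leaves[f]
    for _ in range(leaves.level_j):
        nxt = []
        for i in range(0, len(nodes), 2):
            lo, hi = nodes[i], nodes[i + 1]
            out = np.empty(2 * len(lo))
            out[0::2] = (lo + hi) / np.sqrt(2.0)
            out[1::2] = (lo - hi) / np.sqrt(2.0)
            nxt.append(out)
        nodes = nxt
    return nodes[0]


def band_frequency_range(m: int, j: int = DEFAULT_LEVEL, fs: float = DEFAULT_FS) -> tuple[float, float]:
    """Frequency interval ``[(m-1)*fs/2**(j+1), m*fs/2**(j+1)]`` of leaf ``m``.

    ``m`` is the 1-based frequency-ordered leaf index, ``1 <= m <= 2**j``.
    At ``j=6`` and ``fs=100`` every leaf spans 0.78125 Hz and leaf 64 ends at
    the 50 Hz Nyquist frequency.
    """
    if not (1 <= m <= 2**j):
        raise ValidationError(f"leaf index m={m} outside 1..{2**j}")
    width = fs / 2 ** (j + 1)
    return ((m - 1) * width, m * width)


def leaf_center_frequencies(level: int = DEFAULT_LEVEL, fs: float = DEFAULT_FS) -> np.ndarray:
    """Center frequency of every leaf, in frequency order (Hz)."""
    width = fs / 2 ** (level + 1)
    return (np.arange(2**level) + 0.5) * width


def group_bands(leaves: WaveletPacketLeaves) -> dict[str, np.ndarray]:
    """Concatenate the frequency-ordered leaves of each EEG band.

    Only defined for level-6 decompositions, where the band-to-leaf map is
    fixed (see :data:`BAND_LEAVES`).
    """
    if leaves.level_j != DEFAULT_LEVEL:
        raise ValidationError(f"band grouping requires level 6 leaves, got level {leaves.level_j}")
    groups = {}
    for band, (lo, hi) in BAND_LEAVES.items():
        groups[band] = np.concatenate([leaves.leaves[m - 1] for m in range(lo, hi + 1)])
    return groups


def band_powers(groups: dict[str, np.ndarray]) -> BandPowerSummary:
    """Band energies and relative powers from grouped coefficients.

    ``pwr[k]`` is the sum of squared coefficients of band ``k``;
    ``pwr_total`` sums the four bands (leaves outside every band do not
    contribute); ``relpwr[k] = pwr[k] / pwr_total``.

    Raises
    ------
    DegenerateInputError
        If the total band energy is zero, in which case the relative power
        distribution is undefined.
    """
    if not groups:
        raise ValidationError("empty band groups")
    pwr = {band: float(np.sum(np.square(d))) for band, d in groups.items()}
    pwr_total = float(sum(pwr.values()))
    if pwr_total == 0.0:
        raise DegenerateInputError("zero total band energy: relative power undefined")
    relpwr = {band: p / pwr_total for band, p in pwr.items()}
    return BandPowerSummary(pwr=pwr, pwr_total=pwr_total, relpwr=relpwr, band_map=dict(BAND_LEAVES))
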