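"""The canonical 51-feature vector of one analysis epoch.

Per EEG channel (Fpz-Cz = EEG1, Pz-Oz = EEG2) 25 features are computed on
each 128-sample segment and averaged over the epoch's segments:

* 4 statistical moments (mean, standard deviation, skewness, kurtosis; all
  population-normalised, skewness/kurtosis scaled by sigma^3 / sigma^4),
* 1 interval feature (zero-crossing count),
* 4 absolute band spectra (ABS*, mean absolute wavelet-packet coefficient of
  the band),
* 4 relative band powers (REL*, squared-coefficient band energy over the
  four-band total),
* 4 band-ratio features computed from the ABS values: alpha/beta, theta/beta,
  (theta+alpha)/beta and (theta+alpha)/(alpha+beta),
* 4 center-of-gravity frequencies (CGF*, energy-weighted mean leaf frequency
  of the band) and 4 frequency variabilities (FV*, the corresponding
  energy-weighted variance).

The 51st feature, RGPNG, is the respiration regularity: the height of the
first nonzero-lag peak of the normalised respiration autocorrelation.

Degenerate inputs (flat segments, empty bands) yield NaN for the affected
features with a warning rather than aborting the epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .signal_io import Epoch
from .wpt import (
    BAND_LEAVES,
    BANDS,
    WaveletPacketLeaves,
    band_powers,
    group_bands,
    haar_wpt,
    leaf_center_frequencies,
)

CHANNELS = ("EEG1", "EEG2")


def _channel_feature_names(ch: str) -> list[str]:
    names = [f"M{ch}", f"STD{ch}", f"SK{ch}", f"KR{ch}", f"ZC{ch}"]
    names += [f"ABS{b.upper()} {ch}" for b in BANDS]
    names += [f"REL{b.upper()} {ch}" for b in BANDS]
    names += [f"ABRATIO {ch}", f"TBRATIO {ch}", f"TABRATIO {ch}", f"TAABRATIO {ch}"]
    names += [f"CGF{b.upper()} {ch}" for b in BANDS]
    names += [f"FV{b.upper()} {ch}" for b in BANDS]
    return names


#: frozen canonical order of the 51 features
FEATURE_NAMES: tuple[str, ...] = tuple(
    _channel_feature_names("EEG1") + _channel_feature_names("EEG2") + ["RGPNG"]
)
assert len(FEATURE_NAMES) == 51


@dataclass
class StatisticalFeatures:
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    n: int


@dataclass
class BandSpectralFeatures:
    abs_psd: dict[str, float]
    rel_psd: dict[str, float]
    abratio: float
    tbratio: float
    tabratio: float
    taabratio: float
    cgf: dict[str, float]
    fv: dict[str, float]


def statistical_features(segment: np.ndarray) -> StatisticalFeatures:
    """Population mean, sd, skewness and kurtosis of one segment.

    Skewness is the third central moment over ``sd**3``; kurtosis the fourth
    over ``sd**4`` (a normal sample gives ~3, not 0).
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 samples")
    mean = float(x.mean())
    centered = x - mean
    var = float(np.mean(centered**2))
    sd = np.sqrt(var)
    if sd == 0.0:
        raise DegenerateInputError("zero variance: skewness/kurtosis undefined")
    skew = float(np.mean(centered**3)) / sd**3
    kurt = float(np.mean(centered**4)) / sd**4
    return StatisticalFeatures(mean=mean, sd=sd, skewness=skew, kurtosis=kurt, n=x.size)


def zero_crossings(segment: np.ndarray) -> int:
    """Count strict sign changes between consecutive samples; zeros inherit the previous sign."""
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 samples")
    signs = np.sign(x)
    # propagate the previous non-zero sign through exact zeros
    for i in range(1, len(signs)):
        if signs[i] == 0:
            signs[i] = signs[i - 1]
    nz = signs[signs != 0]
    if nz.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(nz)))


def respiration_regularity(resp_window: np.ndarray) -> float:
    """Height of the first nonzero-lag peak of the normalised autocorrelation.

    The lag-0 peak is always 1; the next local maximum measures how strictly
    periodic breathing is over the window (1 = perfectly regular, ~0 =
    unstructured).  Returns 0 with a warning when no nonzero-lag local
    maximum exists.
    """
    x = np.asarray(resp_window, dtype=float)
    if x.size < 3:
        raise ValidationError("respiration window too short")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise DegenerateInputError("zero-variance respiration window")
    r = np.correlate(x, x, mode="full")[x.size - 1 :] / denom
    # local maxima at lag > 0
    interior = (r[1:-1] > r[:-2]) & (r[1:-1] >= r[2:])
    peaks = np.flatnonzero(interior) + 1
    if peaks.size == 0:
        warnings.warn("no nonzero-lag autocorrelation peak; regularity set to 0")
        return 0.0
    return float(r[peaks].max())


def spectral_features(leaves: WaveletPacketLeaves) -> BandSpectralFeatures:
    """Band spectral features from one segment's level-6 leaves.

    ABS is the mean absolute coefficient of the band; REL the squared-sum
    band energy over the four-band total; the ratio features are quotients of
    ABS values; CGF/FV are the mean and variance of the band's per-leaf
    energy distribution over the leaf center frequencies.
    """
    groups = group_bands(leaves)
    summary = band_powers(groups)  # raises DegenerateInputError on zero total
    abs_psd = {b: float(np.mean(np.abs(groups[b]))) for b in BANDS}

    def ratio(num: float, den: float) -> float:
        if den == 0.0:
            raise DegenerateInputError("zero denominator in band ratio")
        return num / den

    a, b_, t = abs_psd["alpha"], abs_psd["beta"], abs_psd["theta"]
    ratios = dict(
        abratio=ratio(a, b_),
        tbratio=ratio(t, b_),
        tabratio=ratio(t + a, b_),
        taabratio=ratio(t + a, a + b_),
    )

    energies = leaves.leaf_energies()
    centers = leaf_center_frequencies(leaves.level_j, leaves.fs)
    cgf: dict[str, float] = {}
    fv: dict[str, float] = {}
    for band, (lo, hi) in BAND_LEAVES.items():
        p = energies[lo - 1 : hi]
        f = centers[lo - 1 : hi]
        total = p.sum()
        if total == 0.0:
            raise DegenerateInputError(f"zero energy in {band} band: CGF/FV undefined")
        mean_f = float(np.dot(p, f) / total)
        cgf[band] = mean_f
        fv[band] = float(np.dot(p, f * f) / total - mean_f**2)

    return BandSpectralFeatures(
        abs_psd=abs_psd, rel_psd=dict(summary.relpwr), cgf=cgf, fv=fv, **ratios
    )


def _channel_segment_features(segment: np.ndarray, fs: float) -> dict[str, float]:
    out: dict[str, float] = {}
    try:
        st = statistical_features(segment)
        out.update(M=st.mean, STD=st.sd, SK=st.skewness, KR=st.kurtosis)
    except DegenerateInputError:
        x = np.asarray(segment, dtype=float)
        out.update(M=float(x.mean()), STD=0.0, SK=np.nan, KR=np.nan)
    out["ZC"] = float(zero_crossings(segment))
    try:
        sp = spectral_features(haar_wpt(segment, fs=fs))
        for b in BANDS:
            out[f"ABS{b.upper()}"] = sp.abs_psd[b]
            out[f"REL{b.upper()}"] = sp.rel_psd[b]
            out[f"CGF{b.upper()}"] = sp.cgf[b]
            out[f"FV{b.upper()}"] = sp.fv[b]
        out.update(
            ABRATIO=sp.abratio, TBRATIO=sp.tbratio, TABRATIO=sp.tabratio, TAABRATIO=sp.taabratio
        )
    except DegenerateInputError:
        for b in BANDS:
            for kind in ("ABS", "REL", "CGF", "FV"):
                out[f"{kind}{b.upper()}"] = np.nan
        for r in ("ABRATIO", "TBRATIO", "TABRATIO", "TAABRATIO"):
            out[r] = np.nan
    return out


def extract_features(epoch: Epoch, eeg_rate: float = 100.0) -> dict[str, float]:
    """The 51 named features of one epoch, in canonical order.

    Per-channel features are computed on each 128-sample segment and averaged
    (NaN-aware) across segments; RGPNG comes from the epoch's respiration
    context window.  Degenerate sub-computations contribute NaN and are
    logged via warnings.
    """
    if not epoch.eeg1_segmented or not epoch.eeg2_segmented:
        raise ValidationError("epoch has no full 128-sample segments")
    values: dict[str, float] = {}
    for ch, segments in (("EEG1", epoch.eeg1_segmented), ("EEG2", epoch.eeg2_segmented)):
        per_seg = [_channel_segment_features(s, eeg_rate) for s in segments]
        for short in per_seg[0]:
            col = np.array([d[short] for d in per_seg])
            if np.all(np.isnan(col)):
                warnings.warn(f"feature {short} {ch} degenerate in every segment of epoch {epoch.index}")
                val = np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    val = float(np.nanmean(col))
            name = f"{short}{ch}" if short in ("M", "STD", "SK", "KR", "ZC") else f"{short} {ch}"
            values[name] = val
    try:
        values["RGPNG"] = respiration_regularity(epoch.resp_window)
    except DegenerateInputError:
        warnings.warn(f"degenerate respiration window in epoch {epoch.index}")
        values["RGPNG"] = np.nan
    return {name: values[name] for name in FEATURE_NAMES}


def feature_matrix(epochs: list[Epoch], eeg_rate: float = 100.0):
    """Feature DataFrame (one row per epoch, canonical columns) plus label column if present."""
    import pandas as pd

    rows = [extract_features(e, eeg_rate) for e in epochs]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    labels = [e.label for e in epochs]
    if all(l is not None for l in labels) and labels:
        df["label"] = [int(l) for l in labels]
    return df
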