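"""The 51-feature inventory: moments, crossings, respiration regularity, band spectra."""

import numpy as np
import pytest

from sleeponset import extract_features, haar_wpt, respiration_regularity
from sleeponset.errors import DegenerateInputError, ValidationError
from sleeponset.features import (
    FEATURE_NAMES,
    spectral_features,
    statistical_features,
    zero_crossings,
)
from sleeponset.signal_io import Epoch
from sleeponset.wpt import WaveletPacketLeaves, leaf_center_frequencies


def make_epoch(eeg1, eeg2, resp, label=None):
    segs1 = [eeg1[k * 128 : (k + 1) * 128] for k in range(len(eeg1) // 128)]
    segs2 = [eeg2[k * 128 : (k + 1) * 128] for k in range(len(eeg2) // 128)]
    return Epoch(
        index=0,
        eeg1_raw=eeg1,
        eeg2_raw=eeg2,
        eeg1_segmented=segs1,
        eeg2_segmented=segs2,
        resp_window=resp,
        resp_rate=1.0,
        label=label,
    )


def leaves_with_energy(values: dict[int, np.ndarray]) -> WaveletPacketLeaves:
    """Hand-built level-6 leaves: ``values`` maps 1-based leaf index -> coefficients."""
    leaves = [np.zeros(2) for _ in range(64)]
    for m, v in values.items():
        leaves[m - 1] = np.asarray(v, dtype=float)
    return WaveletPacketLeaves(level_j=6, fs=100.0, leaves=leaves)


class TestStatisticalFeatures:
    def test_symmetric_sample(self):
        st = statistical_features(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert st.mean == 3.0
        assert st.sd == pytest.approx(np.sqrt(2.0))  # population denominator
        assert st.skewness == pytest.approx(0.0, abs=1e-12)

    def test_normal_sample_kurtosis_near_three(self, rng):
        x = rng.standard_normal(100_000)
        st = statistical_features(x)
        assert st.kurtosis == pytest.approx(3.0, abs=0.1)
        assert st.skewness == pytest.approx(0.0, abs=0.05)

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            statistical_features(np.full(10, 2.0))


class TestZeroCrossings:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([1.0, -1.0, 1.0, -1.0], 3),
            ([1.0, 2.0, 3.0], 0),
            ([1.0, 0.0, -1.0], 1),  # the zero inherits the previous (+) sign
        ],
    )
    def test_examples(self, x, expected):
        assert zero_crossings(np.array(x)) == expected

    def test_one_period_of_sinusoid(self):
        t = np.arange(100) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t + 0.1)
        # brute-force sign scan oracle
        s = np.sign(x[x != 0])
        assert zero_crossings(x) == int(np.count_nonzero(np.diff(s))) == 2


class TestRespirationRegularity:
    def test_pure_sinusoid_near_one(self):
        t = np.arange(60)
        val = respiration_regularity(np.sin(2 * np.pi * t / 4.0))
        # biased autocorrelation tapers the lag-4 peak to ~(1 - 4/60)
        assert val == pytest.approx(1.0 - 4 / 60, abs=0.05)

    def test_white_noise_low(self, rng):
        vals = [respiration_regularity(rng.standard_normal(60)) for _ in range(20)]
        assert np.mean(np.array(vals) < 0.5) >= 0.9

    def test_jitter_reduces_regularity(self, rng):
        t = np.arange(120)
        clean = np.sin(2 * np.pi * t / 4.0)
        jittered = np.sin(2 * np.pi * t / 4.0 + np.cumsum(rng.normal(0, 0.25, 120)))
        assert respiration_regularity(jittered) < respiration_regularity(clean)

    def test_degenerate_window(self):
        with pytest.raises(DegenerateInputError):
            respiration_regularity(np.zeros(60))


class TestSpectralFeatures:
    def test_point_mass_per_band(self):
        # one active leaf per band -> CGF is that leaf's center, FV is zero
        active = {"delta": 3, "theta": 8, "alpha": 14, "beta": 30}
        leaves = leaves_with_energy({m: [1.0, 1.0] for m in active.values()})
        sp = spectral_features(leaves)
        centers = leaf_center_frequencies()
        for band, m in active.items():
            assert sp.cgf[band] == pytest.approx(centers[m - 1])
            assert sp.fv[band] == pytest.approx(0.0, abs=1e-12)

    def test_two_point_distribution_closed_form(self):
        # equal energy in delta leaves 2 and 4 -> CGF midway, FV = ((f2-f1)/2)^2
        leaves = leaves_with_energy(
            {2: [1.0, 0.0], 4: [0.0, 1.0], 8: [1.0, 0.0], 14: [1.0, 0.0], 30: [1.0, 0.0]}
        )
        sp = spectral_features(leaves)
        centers = leaf_center_frequencies()
        f1, f2 = centers[1], centers[3]
        assert sp.cgf["delta"] == pytest.approx((f1 + f2) / 2)
        assert sp.fv["delta"] == pytest.approx(((f2 - f1) / 2) ** 2)

    def test_equal_abs_alpha_beta_gives_unit_ratio(self):
        values = {m: [0.5, 0.5] for m in range(11, 46)}  # alpha and beta leaves equal
        values.update({m: [1.0, 1.0] for m in range(1, 11)})  # delta, theta nonzero
        sp = spectral_features(leaves_with_energy(values))
        assert sp.abratio == pytest.approx(1.0)

    def test_fv_matches_weighted_variance_oracle(self, rng):
        x = rng.normal(size=128)
        leaves = haar_wpt(x)
        sp = spectral_features(leaves)
        centers = leaf_center_frequencies()
        energies = leaves.leaf_energies()
        for band, (lo, hi) in (("delta", (1, 5)), ("beta", (18, 45))):
            f, p = centers[lo - 1 : hi], energies[lo - 1 : hi]
            mean = np.average(f, weights=p)
            var = np.average((f - mean) ** 2, weights=p)
            assert sp.fv[band] == pytest.approx(var, rel=1e-9)

    def test_zero_beta_band_degenerate(self):
        leaves = leaves_with_energy({3: [1.0, 1.0], 8: [1.0, 1.0], 14: [1.0, 1.0]})
        with pytest.raises(DegenerateInputError):
            spectral_features(leaves)


class TestExtractFeatures:
    def test_returns_51_named_features(self, rng):
        eeg = rng.normal(0, 10, 1000)
        fv = extract_features(make_epoch(eeg, rng.normal(0, 10, 1000), np.sin(np.arange(60) / 2)))
        assert list(fv.keys()) == list(FEATURE_NAMES)
        assert len(fv) == 51
        assert all(np.isfinite(v) for v in fv.values())

    def test_identical_channels_give_identical_features(self, rng):
        eeg = rng.normal(0, 10, 1000)
        fv = extract_features(make_epoch(eeg, eeg.copy(), np.sin(np.arange(60) / 2)))
        for name, value in fv.items():
            if name.endswith("EEG1") or name.endswith(" EEG1"):
                twin = name.replace("EEG1", "EEG2")
                assert fv[twin] == pytest.approx(value, rel=1e-12)

    def test_alpha_only_epoch_maximises_alpha_relative_power(self, alpha_only_epoch):
        fv = extract_features(alpha_only_epoch)
        rels = {b: fv[f"REL{b} EEG1"] for b in ("DELTA", "THETA", "ALPHA", "BETA")}
        assert max(rels, key=rels.get) == "ALPHA"

    def test_scale_invariance(self, rng):
        """Gain on a channel scales mean/sd/ABS linearly and leaves the
        dimensionless and frequency features untouched."""
        eeg1 = rng.normal(0, 10, 1000)
        eeg2 = rng.normal(0, 10, 1000)
        resp = np.sin(np.arange(60) / 2)
        base = extract_features(make_epoch(eeg1, eeg2, resp))
        scaled = extract_features(make_epoch(3.7 * eeg1, eeg2, resp))
        for name in FEATURE_NAMES:
            if "EEG2" in name or name == "RGPNG":
                assert scaled[name] == pytest.approx(base[name], rel=1e-9)
            elif name.startswith(("M", "STD", "ABS")):
                assert scaled[name] == pytest.approx(3.7 * base[name], rel=1e-9)
            else:  # SK, KR, ZC, REL, ratios, CGF, FV
                assert scaled[name] == pytest.approx(base[name], rel=1e-9)

    def test_degenerate_epoch_yields_nan_flags(self):
        flat = np.zeros(1000)
        with pytest.warns(UserWarning):
            fv = extract_features(make_epoch(flat, flat, np.sin(np.arange(60) / 2)))
        assert np.isnan(fv["SKEEG1"]) and np.isnan(fv["RELALPHA EEG1"])
        assert fv["ZCEEG1"] == 0.0

    def test_epoch_without_segments_rejected(self):
        ep = make_epoch(np.zeros(100), np.zeros(100), np.zeros(60))
        with pytest.raises(ValidationError):
            extract_features(ep)
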