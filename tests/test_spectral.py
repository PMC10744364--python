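import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from specratio.io import EEGRecording
from specratio.montage import CHANNELS_1020, LobeMap
from specratio.spectral import (
    BAND_NAMES,
    RATIO_NAMES,
    BandScheme,
    InvalidBandError,
    SpectralParams,
    band_power,
    cohort_band_powers_multi,
    decimate_grid,
    lobar_band_power,
    power_ratios,
    welch_psd,
)

THREE_CONFIGS = [(2.0, 10), (2.0, 5), (1.0, 10)]


class TestSpectralParams:
    @pytest.mark.parametrize(
        "window_s, steps, expected",
        [
            (2.0, 10, (1000, 5000, 500)),
            (2.0, 5, (1000, 2500, 500)),
            (1.0, 10, (500, 5000, 250)),
        ],
    )
    def test_sample_count_decomposition_at_500hz(self, window_s, steps, expected):
        p = SpectralParams(window_s=window_s, steps_per_hz=steps, fs=500.0)
        assert (p.nperseg, p.nfft, p.noverlap) == expected
        assert p.df == pytest.approx(1.0 / steps)

    def test_fft_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            SpectralParams(window_s=4.0, steps_per_hz=1, fs=500.0)


class TestWelchPSD:
    def test_matches_scipy_welch(self, rng):
        """The batched implementation must agree with scipy.signal.welch
        (same taper, overlap, padding, detrending, density scaling)."""
        x = rng.standard_normal((2, 4000))
        p = SpectralParams(window_s=2.0, steps_per_hz=10, fs=500.0)
        f, psd = welch_psd(x, p)
        f2, psd2 = sps.welch(
            x, fs=500.0, window="hamming", nperseg=1000, noverlap=500,
            nfft=5000, detrend="constant", scaling="density", axis=-1,
        )
        np.testing.assert_allclose(f, f2)
        np.testing.assert_allclose(psd, psd2, rtol=1e-10, atol=1e-14)

    def test_sinusoid_concentration_matches_taper_oracle(self):
        """A 10 Hz sinusoid's spectral mass near the line must equal the
        analytic concentration of the Hamming taper's transform."""
        p = SpectralParams(window_s=2.0, steps_per_hz=10, fs=500.0)
        t = np.arange(20 * 500) / 500.0
        f, psd = welch_psd(np.sin(2 * np.pi * 10 * t), p)
        measured = psd[(f >= 9.5) & (f <= 10.5)].sum() / psd.sum()
        # oracle: squared magnitude of the zero-padded Hamming transform
        # shifted to 10 Hz, integrated over 10 +- 0.5 Hz
        win = sps.get_window("hamming", p.nperseg)
        W = np.abs(np.fft.fft(win * np.exp(2j * np.pi * 10 * np.arange(p.nperseg) / 500.0), p.nfft)) ** 2
        grid = np.fft.fftfreq(p.nfft, d=1 / 500.0)
        oracle = W[np.abs(grid - 10) <= 0.5].sum() / W.sum()
        assert measured == pytest.approx(oracle, abs=0.01)
        assert measured > 0.95

    def test_white_noise_flat(self, rng):
        p = SpectralParams(window_s=1.0, steps_per_hz=5, fs=200.0)
        x = rng.standard_normal(400 * 200)
        f, psd = welch_psd(x, p)
        sel = (f >= 2.5) & (f <= 97.5)
        binned = [
            psd[(f >= lo) & (f < lo + 5)].mean() for lo in np.arange(2.5, 95, 5)
        ]
        assert max(binned) / min(binned) <= 1.2
        assert sel.any()

    def test_zero_signal_zero_spectrum(self):
        p = SpectralParams(window_s=1.0, steps_per_hz=5, fs=100.0)
        _, psd = welch_psd(np.zeros(1000), p)
        assert np.all(psd == 0)

    def test_short_signal_rejected(self):
        p = SpectralParams(window_s=2.0, steps_per_hz=10, fs=500.0)
        with pytest.raises(ValueError, match="shorter than one window"):
            welch_psd(np.zeros(999), p)

    def test_parseval_consistency(self, rng):
        """Sum of the density over the grid times the spacing approximates
        the signal variance (stationary noise, long record)."""
        p = SpectralParams(window_s=2.0, steps_per_hz=10, fs=250.0)
        x = rng.standard_normal(200 * 250)
        f, psd = welch_psd(x, p)
        total = psd.sum() * p.df
        assert total == pytest.approx(x.var(), rel=0.05)


class TestBandScheme:
    def test_edges_cover_study_range(self):
        scheme = BandScheme()
        assert scheme.intervals == {
            "delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
            "beta": (13.0, 30.0), "gamma": (30.0, 45.0),
        }

    def test_no_grid_point_double_counted(self):
        scheme = BandScheme()
        freqs = np.arange(0, 50.0001, 0.1)
        total = sum(scheme.mask(freqs, b).sum() for b in scheme.names)
        combined = (freqs >= 0.5) & (freqs <= 45.0)
        assert total == combined.sum()


class TestBandPower:
    def test_constant_spectrum(self):
        freqs = np.arange(0, 50.0, 0.2)
        psd = np.full(freqs.size, 3.7)
        for band in BAND_NAMES:
            assert band_power(freqs, psd, band) == pytest.approx(3.7)

    def test_sinusoid_alpha_dominates(self):
        p = SpectralParams(window_s=2.0, steps_per_hz=10, fs=500.0)
        t = np.arange(12 * 500) / 500.0
        f, psd = welch_psd(np.sin(2 * np.pi * 10 * t), p)
        alpha = band_power(f, psd, "alpha")
        others = [band_power(f, psd, b) for b in BAND_NAMES if b != "alpha"]
        assert all(alpha >= 100 * o for o in others)

    def test_band_outside_grid_rejected(self):
        freqs = np.arange(0, 45.0, 0.1)
        with pytest.raises(InvalidBandError):
            band_power(freqs, np.ones(freqs.size), (50.0, 60.0))


class TestLobarBandPower:
    def _uniform_recording(self, rng, fs=250.0, seconds=12):
        x = rng.standard_normal(int(fs * seconds))
        data = np.tile(x, (19, 1))
        return EEGRecording(data, fs, list(CHANNELS_1020))

    def test_identical_channels_give_equal_lobes(self, rng):
        rec = self._uniform_recording(rng)
        p = SpectralParams(window_s=2.0, steps_per_hz=5, fs=250.0)
        row = lobar_band_power(rec, p)
        for band in BAND_NAMES:
            assert row[f"F-{band}"] == pytest.approx(row[f"T-{band}"], rel=1e-9)

    def test_missing_electrode_is_named(self, rng):
        labels = [ch for ch in CHANNELS_1020 if ch != "T5"]
        rec = EEGRecording(rng.standard_normal((18, 3000)), 250.0, labels)
        p = SpectralParams(window_s=2.0, steps_per_hz=5, fs=250.0)
        with pytest.raises(ValueError, match="T5"):
            lobar_band_power(rec, p)

    def test_scale_equivariance_and_ratio_invariance(self, rng):
        """Scaling the recording by c scales every band power by c^2 and
        leaves every ratio unchanged."""
        rec = EEGRecording(
            rng.standard_normal((19, 4000)), 250.0, list(CHANNELS_1020)
        )
        p = SpectralParams(window_s=2.0, steps_per_hz=5, fs=250.0)
        row1 = lobar_band_power(rec, p)
        rec3 = EEGRecording(3.0 * rec.data, 250.0, list(CHANNELS_1020))
        row3 = lobar_band_power(rec3, p)
        np.testing.assert_allclose(row3.to_numpy(), 9.0 * row1.to_numpy(),
                                   rtol=1e-9)
        r1 = power_ratios(row1.to_frame().T)
        r3 = power_ratios(row3.to_frame().T)
        np.testing.assert_allclose(r3.to_numpy(), r1.to_numpy(), rtol=1e-9)


class TestPowerRatios:
    def _table(self, values):
        cols = [f"{lobe}-{b}" for lobe in ("F", "T") for b in BAND_NAMES]
        return pd.DataFrame([values], columns=cols, index=["s1"])

    def test_exactly_65_named_ratios(self):
        assert len(RATIO_NAMES) == 65
        inter = [n for n in RATIO_NAMES if n.startswith("F-") and "/T-" in n]
        intra_f = [n for n in RATIO_NAMES if n.startswith("F-") and "/F-" in n]
        intra_t = [n for n in RATIO_NAMES if n.startswith("T-") and "/T-" in n]
        assert (len(inter), len(intra_f), len(intra_t)) == (25, 20, 20)

    def test_all_equal_powers_give_unit_ratios(self):
        rt = power_ratios(self._table([2.5] * 10))
        assert np.allclose(rt.to_numpy(), 1.0)

    def test_arithmetic(self):
        vals = [1.0] * 10
        cols = [f"{lobe}-{b}" for lobe in ("F", "T") for b in BAND_NAMES]
        vals[cols.index("F-theta")] = 2.0
        vals[cols.index("T-alpha")] = 0.5
        rt = power_ratios(self._table(vals))
        assert rt.loc["s1", "F-theta/T-alpha"] == pytest.approx(4.0)

    def test_reciprocal_identity(self, rng):
        vals = rng.uniform(0.5, 5.0, 10)
        rt = power_ratios(self._table(vals))
        prod = rt["F-theta/F-alpha"] * rt["F-alpha/F-theta"]
        assert prod.iloc[0] == pytest.approx(1.0, rel=1e-12)

    def test_zero_denominator_flagged_missing(self):
        vals = [1.0] * 10
        cols = [f"{lobe}-{b}" for lobe in ("F", "T") for b in BAND_NAMES]
        vals[cols.index("T-alpha")] = 0.0
        rt = power_ratios(self._table(vals))
        assert np.isnan(rt.loc["s1", "F-theta/T-alpha"])
        assert rt.loc["s1", "T-alpha/T-theta"] == 0.0


def test_decimate_grid_matches_direct_coarse_welch(rng):
    """Subsampling a 10-steps-per-Hz spectrum at every 2nd bin must equal
    the directly computed 5-steps-per-Hz spectrum (zero-padding identity)."""
    x = rng.standard_normal((3, 6000))
    fine = SpectralParams(window_s=2.0, steps_per_hz=10, fs=500.0)
    coarse = SpectralParams(window_s=2.0, steps_per_hz=5, fs=500.0)
    f_f, p_f = welch_psd(x, fine)
    f_c, p_c = welch_psd(x, coarse)
    f_d, p_d = decimate_grid(f_f, p_f, 2)
    np.testing.assert_allclose(f_d, f_c)
    np.testing.assert_allclose(p_d, p_c, rtol=1e-10, atol=1e-14)


def test_multi_config_tables_match_single_config(small_cohort):
    _, recordings, subjects = small_cohort
    from specratio.spectral import cohort_band_powers

    params = [SpectralParams(window_s=w, steps_per_hz=s, fs=500.0)
              for w, s in THREE_CONFIGS]
    tabs = cohort_band_powers_multi(recordings, subjects, params)
    for p in params:
        direct = cohort_band_powers(recordings, subjects, p)
        np.testing.assert_allclose(
            tabs[p][direct.columns].to_numpy(), direct.to_numpy(), rtol=1e-9
        )
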