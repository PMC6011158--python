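import numpy as np
import pytest
from scipy import signal as sps

from cautoreg.preprocess import Segment
from cautoreg.tfa import (
    TfaSettings,
    band_average,
    critical_coherence,
    run_tfa,
    transfer_function,
    welch_spectra,
)


def make_segment(x, y, fs=10.0):
    return Segment(x, y, fs, float(np.mean(x)), float(np.mean(y)))


class TestSettings:
    def test_defaults(self):
        s = TfaSettings()
        assert s.nperseg == 1000 and s.step == 500

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"overlap_frac": 0.0},
            {"overlap_frac": 1.0},
            {"smooth_points": 2},
            {"smooth_points": 0},
            {"bands": (("a", 0.05, 0.02),)},
            {"bands": (("a", 0.02, 0.1), ("b", 0.05, 0.2))},
        ],
    )
    def test_invalid_settings(self, kwargs):
        with pytest.raises(ValueError):
            TfaSettings(**kwargs)


class TestWelchSpectra:
    def test_window_count(self):
        x = np.random.default_rng(0).standard_normal(3000)
        *_, n_windows = welch_spectra(x, x, TfaSettings())
        assert n_windows == 5  # (3000 - 1000)/500 + 1

    def test_matches_scipy_csd_without_smoothing(self):
        # independent oracle: scipy's Welch implementation, same settings
        rng = np.random.default_rng(1)
        x = rng.standard_normal(3000)
        y = rng.standard_normal(3000)
        settings = TfaSettings(smooth_points=1)
        Sxx, Syy, Sxy, freqs, _ = welch_spectra(x, y, settings)
        kw = dict(fs=10.0, window="hann", nperseg=1000, noverlap=500,
                  detrend="constant", scaling="density")
        f_ref, Pxx = sps.welch(x, **kw)
        _, Pyy = sps.welch(y, **kw)
        _, Pxy = sps.csd(x, y, **kw)
        np.testing.assert_allclose(freqs, f_ref)
        np.testing.assert_allclose(Sxx, Pxx, rtol=1e-10)
        np.testing.assert_allclose(Syy, Pyy, rtol=1e-10)
        np.testing.assert_allclose(Sxy, Pxy, rtol=1e-10)

    def test_self_cross_spectrum_is_auto_spectrum(self):
        x = np.random.default_rng(2).standard_normal(3000)
        Sxx, Syy, Sxy, _, _ = welch_spectra(x, x, TfaSettings())
        np.testing.assert_allclose(Sxy.imag, 0, atol=1e-12)
        np.testing.assert_allclose(Sxy.real, Sxx, rtol=1e-12)
        np.testing.assert_allclose(Syy, Sxx, rtol=1e-12)

    def test_tone_parseval(self):
        t = np.arange(3000) / 10.0
        x = np.sin(2 * np.pi * 0.1 * t)
        Sxx, _, _, freqs, _ = welch_spectra(x, x, TfaSettings())
        total = np.sum(Sxx) * (freqs[1] - freqs[0])
        assert total == pytest.approx(0.5, rel=0.05)

    def test_input_shorter_than_window(self):
        with pytest.raises(ValueError, match="shorter than one window"):
            welch_spectra(np.zeros(500), np.zeros(500), TfaSettings())

    def test_unequal_lengths(self):
        with pytest.raises(ValueError, match="equal length"):
            welch_spectra(np.zeros(3000), np.zeros(2999), TfaSettings())


class TestTransferFunction:
    def test_pure_scaling(self):
        x = np.random.default_rng(3).standard_normal(3000)
        Sxx, Syy, Sxy, freqs, _ = welch_spectra(x, 2 * x, TfaSettings())
        coh, gain, phase = transfer_function(Sxx, Syy, Sxy)
        sel = (freqs > 0.01) & (freqs < 4.9)
        np.testing.assert_allclose(coh[sel], 1.0, atol=1e-10)
        np.testing.assert_allclose(gain[sel], 2.0, rtol=1e-9)
        np.testing.assert_allclose(phase[sel], 0.0, atol=1e-7)

    def test_delay_phase_law(self):
        # output delayed by 1 s: phase = -360 * f degrees
        rng = np.random.default_rng(4)
        x = rng.standard_normal(3100)
        y = x[:-10]  # y(t) = x(t - 1 s) at 10 Hz
        x = x[10:]
        settings = TfaSettings()
        Sxx, Syy, Sxy, freqs, _ = welch_spectra(x, y, settings)
        coh, gain, phase = transfer_function(Sxx, Syy, Sxy)
        idx = np.argmin(np.abs(freqs - 0.1))
        assert phase[idx] == pytest.approx(-36.0, abs=2.0)
        assert gain[idx] == pytest.approx(1.0, rel=0.05)

    def test_zero_spectrum_bins_flagged_nan(self):
        Sxx = np.array([0.0, 1.0, 2.0])
        Syy = np.array([1.0, 1.0, 2.0])
        Sxy = np.array([0.0 + 0j, 0.5 + 0j, 1.0 + 0j])
        coh, gain, phase = transfer_function(Sxx, Syy, Sxy)
        assert np.isnan(coh[0]) and np.isnan(gain[0]) and np.isnan(phase[0])
        assert np.isfinite(coh[1:]).all()

    def test_swap_inverts_gain_and_negates_phase(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(3000)
        y = np.roll(x, 3) * 2.0
        settings = TfaSettings()
        fwd = transfer_function(*welch_spectra(x, y, settings)[:3])
        rev = transfer_function(*welch_spectra(y, x, settings)[:3])
        freqs = welch_spectra(x, y, settings)[3]
        sel = (freqs >= 0.02) & (freqs < 0.2)
        # exact identity: gain_fwd * gain_rev = coherence, so at coherent
        # bins (coh ~ 1) the reverse gain inverts the forward gain
        np.testing.assert_allclose(rev[1][sel], fwd[0][sel] / fwd[1][sel], rtol=1e-9)
        np.testing.assert_allclose(rev[2][sel], -fwd[2][sel], atol=1e-9)

    def test_coherence_bounded(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            x = rng.standard_normal(2500)
            y = rng.standard_normal(2500) + 0.3 * x
            coh, gain, _ = transfer_function(*welch_spectra(x, y, TfaSettings())[:3])
            valid = np.isfinite(coh)
            assert np.all(coh[valid] >= 0) and np.all(coh[valid] <= 1 + 1e-12)
            assert np.all(gain[np.isfinite(gain)] >= 0)

    def test_scaling_invariances(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(3000)
        y = rng.standard_normal(3000) + 0.5 * x
        settings = TfaSettings()
        base = transfer_function(*welch_spectra(x, y, settings)[:3])
        scaled_out = transfer_function(*welch_spectra(x, 3 * y, settings)[:3])
        scaled_in = transfer_function(*welch_spectra(4 * x, y, settings)[:3])
        np.testing.assert_allclose(scaled_out[1], 3 * base[1], rtol=1e-9)  # gain linear in y
        np.testing.assert_allclose(scaled_out[0], base[0], rtol=1e-9)  # coherence invariant
        np.testing.assert_allclose(scaled_in[2], base[2], atol=1e-9)  # phase invariant
        np.testing.assert_allclose(scaled_out[2], base[2], atol=1e-9)


class TestBandAverage:
    FREQS = np.arange(0, 0.3, 0.01)

    def test_constant(self):
        values = np.full_like(self.FREQS, 3.3)
        assert band_average(values, self.FREQS, (0.02, 0.07)) == pytest.approx(3.3)

    def test_single_bin(self):
        values = np.arange(len(self.FREQS), dtype=float)
        assert band_average(values, self.FREQS, (0.05, 0.06)) == 5.0

    def test_linear_ramp_midpoint(self):
        values = np.zeros_like(self.FREQS)
        band = (0.02, 0.07)  # bins 0.02..0.06
        values[2:7] = np.linspace(1.0, 3.0, 5)
        assert band_average(values, self.FREQS, band) == pytest.approx(2.0)

    def test_empty_band(self):
        with pytest.raises(ValueError, match="no valid bins"):
            band_average(np.zeros_like(self.FREQS), self.FREQS, (0.001, 0.005))

    def test_nan_bins_excluded(self):
        values = np.ones_like(self.FREQS)
        values[3] = np.nan
        assert band_average(values, self.FREQS, (0.02, 0.07)) == pytest.approx(1.0)

    def test_phase_wraparound(self):
        values = np.zeros_like(self.FREQS)
        values[2:7] = [170.0, 175.0, -180.0, -175.0, -170.0]
        avg = band_average(values, self.FREQS, (0.02, 0.07), circular=True)
        assert avg == pytest.approx(180.0, abs=1e-9)


class TestCriticalCoherence:
    def test_paper_settings_threshold(self):
        value = critical_coherence(n_sim=1500, seed=0)
        assert value == pytest.approx(0.34, abs=0.04)

    def test_more_windows_lower_threshold(self):
        five = critical_coherence(n_sim=800, seed=1, duration_s=300)
        many = critical_coherence(n_sim=800, seed=1, duration_s=1300)  # 25 windows
        assert many < five

    def test_more_smoothing_lower_threshold(self):
        narrow = critical_coherence(TfaSettings(smooth_points=1), n_sim=800, seed=2)
        wide = critical_coherence(TfaSettings(smooth_points=5), n_sim=800, seed=2)
        assert wide < narrow

    def test_single_window_degenerate(self):
        value = critical_coherence(
            TfaSettings(smooth_points=1), n_sim=50, seed=0, duration_s=100
        )
        assert value == pytest.approx(1.0, abs=1e-9)

    def test_alpha_monotone(self):
        strict = critical_coherence(n_sim=800, seed=3, alpha=0.05)
        lax = critical_coherence(n_sim=800, seed=3, alpha=0.5)
        assert lax < strict

    def test_reproducible(self):
        a = critical_coherence(n_sim=300, seed=5)
        b = critical_coherence(n_sim=300, seed=5)
        assert a == b

    def test_bad_mode(self):
        with pytest.raises(ValueError, match="mode"):
            critical_coherence(n_sim=10, mode="pooled")


class TestRunTfa:
    def test_identity_channels(self):
        rng = np.random.default_rng(8)
        x = 90 + rng.standard_normal(3000)
        result = run_tfa(make_segment(x, x))
        assert result.n_windows == 5
        for band in result.band_results.values():
            assert band.coherence == pytest.approx(1.0, abs=1e-9)
            assert band.gain == pytest.approx(1.0, rel=1e-9)
            assert band.phase_deg == pytest.approx(0.0, abs=1e-6)
            assert band.reliable

    def test_independent_channels_unreliable(self):
        rng = np.random.default_rng(9)
        unreliable = 0
        n_trials = 40
        for _ in range(n_trials):
            x = 90 + rng.standard_normal(3000)
            y = 50 + rng.standard_normal(3000)
            result = run_tfa(make_segment(x, y))
            if not any(b.reliable for b in result.band_results.values()):
                unreliable += 1
        assert unreliable >= 0.75 * n_trials

    def test_fs_mismatch(self):
        x = np.random.default_rng(0).standard_normal(3000)
        with pytest.raises(ValueError, match="Hz"):
            run_tfa(make_segment(x, x, fs=200.0))
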