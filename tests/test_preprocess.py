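"""Optical chain: OD, motion correction, filtering, Beer-Lambert, GLM."""

import numpy as np
import pytest
from scipy import signal as sps

from nirsvar.preprocess import (
    PreprocessConfig,
    default_layout,
    intensity_to_od,
    motion_correct,
    bandpass,
    od_to_haemo,
    hrf_double_gamma,
    short_channel_glm,
    baseline_correct,
    extract_window,
    BandpassFilter,
    WaveletMotionCorrector,
)
from nirsvar.protocols import make_protocol

FS = 7173.0 / 705.0


def _forward_od(hbo, hbr, channel, layout, wl):
    eps_hbo, eps_hbr = layout.extinction[wl]
    d_cm = channel.distance_m * 100.0
    return (eps_hbo * hbo + eps_hbr * hbr) * 1e-6 * d_cm * layout.dpf[wl]


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        assert np.allclose(intensity_to_od(np.full(100, 2.5)), 0.0)

    def test_halved_intensity_jumps_log10_two(self):
        x = np.ones(101)
        x[50] = 0.5
        od = intensity_to_od(x)
        assert od[50] - od[0] == pytest.approx(np.log10(2.0), abs=1e-12)

    def test_nonpositive_intensity_reports_index(self):
        x = np.ones((2, 10))
        x[1, 3] = 0.0
        with pytest.raises(ValueError, match=r"\(1, 3\)"):
            intensity_to_od(x)


class TestBeerLambert:
    def test_zero_od_gives_zero_concentrations(self):
        layout = default_layout()
        ch = layout.long_channels[0]
        hbo, hbr = od_to_haemo({760: np.zeros(10), 850: np.zeros(10)}, ch, layout)
        assert np.allclose(hbo, 0) and np.allclose(hbr, 0)

    def test_unit_hbo_round_trip(self):
        layout = default_layout()
        ch = layout.long_channels[0]
        od = {wl: _forward_od(np.ones(5), np.zeros(5), ch, layout, wl) for wl in (760, 850)}
        hbo, hbr = od_to_haemo(od, ch, layout)
        assert np.allclose(hbo, 1.0, atol=1e-9)
        assert np.allclose(hbr, 0.0, atol=1e-9)

    def test_random_pairs_round_trip(self, rng):
        layout = default_layout()
        ch = layout.long_channels[0]
        for _ in range(100):
            c = rng.normal(0, 2, size=2)
            od = {wl: _forward_od(c[0], c[1], ch, layout, wl) * np.ones(1) for wl in (760, 850)}
            hbo, hbr = od_to_haemo(od, ch, layout)
            assert abs(hbo[0] - c[0]) < 1e-9
            assert abs(hbr[0] - c[1]) < 1e-9

    def test_missing_wavelength_rejected(self):
        layout = default_layout()
        with pytest.raises(ValueError, match="850"):
            od_to_haemo({760: np.zeros(5)}, layout.long_channels[0], layout)


class TestMotionCorrection:
    def test_zero_series_stays_zero(self):
        assert np.allclose(motion_correct(np.zeros(512)), 0.0)

    def test_smooth_oscillation_preserved(self):
        t = np.arange(4096) / FS
        x = np.sin(2 * np.pi * 0.02 * t)
        out = motion_correct(x)
        assert np.corrcoef(out, x)[0, 1] >= 0.99

    def test_spike_error_halved(self):
        t = np.arange(4096) / FS
        clean = np.sin(2 * np.pi * 0.02 * t)
        spiky = clean.copy()
        spiky[2000:2008] += 10.0
        out = motion_correct(spiky)
        err_before = np.abs(spiky[2000:2008] - clean[2000:2008]).mean()
        err_after = np.abs(out[2000:2008] - clean[2000:2008]).mean()
        assert err_after <= 0.5 * err_before

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            motion_correct(np.zeros(8))


class TestBandpass:
    def test_dc_rejected(self):
        out = bandpass(np.full(4000, 7.0), fs=FS)
        assert np.abs(out).max() <= 1e-8 * 7.0

    def test_designed_passband_gain(self):
        cfg = PreprocessConfig()
        sos = sps.butter(cfg.filter_order, cfg.band, btype="bandpass", fs=FS, output="sos")
        w, h = sps.sosfreqz(sos, worN=[0.02], fs=FS)
        gain = np.abs(h[0]) ** 2  # forward-backward application squares it
        assert 0.9 <= gain <= 1.0

    def test_designed_stopband_attenuation(self):
        cfg = PreprocessConfig()
        sos = sps.butter(cfg.filter_order, cfg.band, btype="bandpass", fs=FS, output="sos")
        w, h = sps.sosfreqz(sos, worN=[1.0], fs=FS)
        atten_db = -20 * np.log10(np.abs(h[0]) ** 2)
        assert atten_db >= 20.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            bandpass(np.zeros(100), band=(0.05, 6.0), fs=FS)


class TestShortChannelGLM:
    def _task_reg(self, n):
        box = np.zeros(n)
        box[n // 4 : n // 2] = 1.0
        return np.convolve(box, hrf_double_gamma(FS))[:n]

    def test_pure_short_channel_removed(self, rng):
        n = 2000
        short = np.cumsum(rng.normal(0, 0.1, n))
        cleaned, diag = short_channel_glm(short.copy(), short[None, :], self._task_reg(n))
        assert np.sqrt(np.mean(cleaned**2)) <= 1e-6 * np.sqrt(np.mean(short**2))

    def test_neural_signal_retained(self, rng):
        n = 3000
        neural = 0.5 * self._task_reg(n) / max(self._task_reg(n).max(), 1e-9)
        short = bandpass(rng.normal(size=n), (0.005, 0.05), 3, FS)
        t = np.linspace(-1, 1, n)
        long = neural + 0.8 * short + 0.5 * t**2
        cleaned, _ = short_channel_glm(long, short[None, :], self._task_reg(n))
        assert np.corrcoef(cleaned, neural)[0, 1] >= 0.95

    def test_best_correlated_short_selected(self, rng):
        n = 2000
        target = bandpass(rng.normal(size=n), (0.005, 0.05), 3, FS)
        decoy = bandpass(rng.normal(size=n), (0.005, 0.05), 3, FS)
        long = target + 0.05 * rng.normal(size=n)
        shorts = np.vstack([decoy, target])
        _, diag = short_channel_glm(long, shorts, self._task_reg(n))
        assert diag["selected_short"] == 1


class TestBaselineAndWindow:
    def test_constant_series_zeroed(self):
        out = baseline_correct(np.full(200, 4.2), first_onset_s=10.0, fs=10.0)
        assert np.allclose(out, 0.0)

    def test_baseline_window_mean_becomes_zero(self, rng):
        x = rng.normal(2.0, 1.0, 500)
        out = baseline_correct(x, first_onset_s=20.0, fs=10.0, baseline_window_s=5.0)
        assert out[150:200].mean() == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_prestimulus_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            baseline_correct(np.zeros(100), first_onset_s=0.2, fs=10.0)

    def test_nback_window_has_printed_sample_count(self):
        proto = make_protocol("nback")
        x = np.zeros(int(round(720 * FS)))
        out = extract_window(x, first_onset_s=10.0, protocol=proto, fs=FS)
        assert out.shape[-1] == 7173

    def test_flanker_window_near_printed_count(self):
        proto = make_protocol("flanker")
        x = np.zeros(int(round(625 * FS)))
        out = extract_window(x, first_onset_s=10.0, protocol=proto, fs=FS)
        assert abs(out.shape[-1] - 6208) <= 2

    def test_window_equal_to_recording_is_identity(self, rng):
        proto = make_protocol("nback")
        x = rng.normal(size=int(round(705 * FS)))
        out = extract_window(x, first_onset_s=5.0, protocol=proto, fs=FS)
        assert np.array_equal(out, x)

    def test_window_beyond_recording_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            extract_window(np.zeros(100), 5.0, make_protocol("nback"), FS)


class TestTransformers:
    def test_bandpass_transformer_matches_function(self, rng):
        X = rng.normal(size=(2, 1000))
        est = BandpassFilter(fs=FS)
        assert np.allclose(est.fit_transform(X), bandpass(X, fs=FS))
        assert est.get_params()["fs"] == FS

    def test_motion_transformer_params_round_trip(self):
        est = WaveletMotionCorrector()
        est.set_params(alpha=0.05)
        assert est.get_params()["alpha"] == 0.05
        with pytest.raises(ValueError, match="invalid parameter"):
            est.set_params(bogus=1)
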