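"""Filtering, artifact removal, MBLL, wavelet/spline correction, R peaks."""

import numpy as np
import pytest
from scipy import signal as sps

from neurofuse import _wavelet
from neurofuse.containers import SignalBlock
from neurofuse.errors import (AlignmentError, CorrectionError, DetectionError,
                              InputError, ParameterError)
from neurofuse.preprocess import (FilterSpec, detect_r_peaks, eog_regress,
                                  filter_signal, ica_clean, mbll,
                                  mbll_forward, rereference_average,
                                  run_auto_pipeline, spline_correct,
                                  wavelet_denoise)

from conftest import make_block


def _sine(freq, rate=250.0, dur=10.0, amp=1.0):
    t = np.arange(int(dur * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


def _fft_amp(x, rate, freq):
    """Amplitude of the FFT bin nearest freq (independent oracle)."""
    spec = np.abs(np.fft.rfft(x)) * 2 / len(x)
    freqs = np.fft.rfftfreq(len(x), 1 / rate)
    return spec[np.argmin(np.abs(freqs - freq))]


class TestFilterSignal:
    def test_dc_rejected_by_bandpass(self):
        b = make_block(np.full((1, 2500), 7.5))
        out = filter_signal(b, FilterSpec("bandpass", 2.0, 50.0))
        assert np.max(np.abs(out.data)) < 1e-6 * 7.5

    def test_passband_gain_near_unity(self):
        b = make_block(_sine(10.0))
        out = filter_signal(b, FilterSpec("bandpass", 2.0, 50.0))
        gain = _fft_amp(out.data[0], 250.0, 10.0) / _fft_amp(b.data[0],
                                                             250.0, 10.0)
        assert 0.95 < gain < 1.05

    def test_notch_attenuates_60hz(self):
        b = make_block(_sine(60.0))
        out = filter_signal(b, FilterSpec("notch", 60.0))
        atten = _fft_amp(out.data[0], 250.0, 60.0) / _fft_amp(b.data[0],
                                                              250.0, 60.0)
        assert atten < 10 ** (-20 / 20)  # >= 20 dB down

    def test_zero_phase_no_lag(self):
        b = make_block(_sine(10.0))
        out = filter_signal(b, FilterSpec("bandpass", 2.0, 50.0))
        xc = np.correlate(out.data[0], b.data[0], mode="full")
        assert np.argmax(xc) == len(b.data[0]) - 1  # zero-lag peak

    def test_cutoff_above_nyquist_rejected(self):
        b = make_block(_sine(10.0))
        with pytest.raises(ParameterError):
            filter_signal(b, FilterSpec("bandpass", 2.0, 200.0))


class TestEogRegress:
    def test_known_mixing_removed(self, rng):
        n = 5000
        eog_sig = rng.standard_normal(n)
        brain = _sine(10.0, dur=20.0)[:n]
        eeg = make_block(0.5 * eog_sig + brain)
        eog = make_block(eog_sig, modality="eog")
        out = eog_regress(eeg, eog)
        assert abs(np.corrcoef(out.data[0], eog_sig)[0, 1]) < 0.01
        # residual orthogonal to the regressor
        assert abs(out.data[0] @ eog_sig) < 1e-8 * np.linalg.norm(
            out.data[0]) * np.linalg.norm(eog_sig)

    def test_zero_eog_is_identity(self, rng):
        eeg = make_block(rng.standard_normal((2, 100)))
        out = eog_regress(eeg, make_block(np.zeros(100), modality="eog"))
        np.testing.assert_array_equal(out.data, eeg.data)

    def test_full_projection(self, rng):
        x = rng.standard_normal(500)
        out = eog_regress(make_block(x), make_block(x, modality="eog"))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_rate_mismatch(self, rng):
        with pytest.raises(AlignmentError):
            eog_regress(make_block(np.zeros(100), rate=250.0),
                        make_block(np.zeros(100), rate=100.0,
                                   modality="eog"))


class TestIcaClean:
    def test_blink_removed_background_kept(self, rng):
        n, n_ch = 5000, 8
        sources = rng.standard_normal((n_ch, n))
        blink = np.zeros(n)  # sparse high-kurtosis bursts like eye blinks
        for c in range(100, n, 500):
            blink[c:c + 50] += sps.windows.hann(50) * 30.0
        sources[0] = blink
        A = rng.standard_normal((n_ch, n_ch))
        eeg = make_block(A @ sources)
        ref = make_block(blink, modality="eog")
        clean, rejected = ica_clean(eeg, ref, seed=0)
        assert len(rejected) >= 1
        blink_part = np.outer(A[:, 0], blink)
        background = eeg.data - blink_part
        removed = eeg.data - clean.data
        blink_var_removed = 1 - np.var(blink_part - removed) / np.var(blink_part)
        bg_var_removed = 1 - np.var(background - (clean.data - 0)) / np.var(
            background)
        assert blink_var_removed >= 0.9
        # background mostly intact: cleaned signal still holds >90% of it
        assert np.var(clean.data - blink_part * 0) > 0.8 * np.var(background)

    def test_subgaussian_no_rejections(self, rng):
        n, n_ch = 4000, 4
        sources = rng.uniform(-1, 1, (n_ch, n))  # sub-Gaussian
        eeg = make_block(rng.standard_normal((n_ch, n_ch)) @ sources)
        clean, rejected = ica_clean(eeg, None, seed=0)
        assert rejected == []
        np.testing.assert_allclose(clean.data, eeg.data, atol=1e-6)

    def test_too_few_channels(self, rng):
        with pytest.raises(InputError):
            ica_clean(make_block(rng.standard_normal((2, 1000))), None)


class TestRereference:
    def test_arithmetic(self):
        b = make_block(np.vstack([np.ones(10), 3 * np.ones(10)]))
        out = rereference_average(b)
        np.testing.assert_allclose(out.data[0], -1.0)
        np.testing.assert_allclose(out.data[1], 1.0)

    def test_idempotent(self, rng):
        b = make_block(rng.standard_normal((4, 200)))
        once = rereference_average(b)
        twice = rereference_average(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_column_sums_vanish(self, rng):
        out = rereference_average(make_block(rng.standard_normal((5, 300))))
        assert np.max(np.abs(out.data.sum(axis=0))) < 1e-9

    def test_single_channel_rejected(self):
        with pytest.raises(InputError):
            rereference_average(make_block(np.zeros(10)))


class TestMbll:
    def test_constant_intensity_gives_zero(self):
        b = SignalBlock("fnirs_intensity", np.full((2, 50), 3.0), 10.0,
                        ["a_760", "a_850"])
        out = mbll(b, [760.0, 850.0])
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)
        assert out.chromophore == ["HbO", "HbR"]

    def test_forward_inverse_recovery(self):
        """OD built with exact arithmetic-mean-1 intensity ratios inverts
        to the analytically known concentrations within 1e-9."""
        n = 400
        k = np.arange(n)
        u1 = 1.0 + 0.05 * np.sin(2 * np.pi * 4 * k / n)   # mean exactly 1
        u2 = 1.0 + 0.04 * np.cos(2 * np.pi * 6 * k / n) \
            - 0.04 * np.mean(np.cos(2 * np.pi * 6 * k / n))
        d, dpf = 3.0, 6.0
        od = np.vstack([-np.log10(u1), -np.log10(u2)]) / (d * dpf)
        E = np.array([[1.4866, 3.8437], [2.5264, 1.7986]])
        det = E[0, 0] * E[1, 1] - E[0, 1] * E[1, 0]
        inv = np.array([[E[1, 1], -E[0, 1]], [-E[1, 0], E[0, 0]]]) / det
        expected_uM = (inv @ od) * 1000.0
        intensity = np.vstack([2.0 * u1, 5.0 * u2])
        blk = SignalBlock("fnirs_intensity", intensity, 10.0,
                          ["a_760", "a_850"])
        out = mbll(blk, [760.0, 850.0], dpf=dpf, distance=d)
        scale = np.abs(expected_uM).max()
        np.testing.assert_allclose(out.data, expected_uM, atol=1e-9 * scale)

    def test_forward_model_round_trip_dynamics(self):
        """mbll inverts mbll_forward exactly up to a constant offset."""
        n = 300
        hbo = 0.8 * np.sin(2 * np.pi * 0.1 * np.arange(n) / 10)
        hbr = -0.3 * hbo
        inten = mbll_forward(hbo, hbr, [1.0, 1.0], [760.0, 850.0])
        blk = SignalBlock("fnirs_intensity", inten, 10.0, ["a_760", "a_850"])
        rec = mbll(blk, [760.0, 850.0])
        for got, truth in zip(rec.data, [hbo, hbr]):
            np.testing.assert_allclose(got - got.mean(), truth - truth.mean(),
                                       atol=1e-9)

    def test_equal_wavelengths_singular(self):
        b = SignalBlock("fnirs_intensity", np.ones((2, 50)), 10.0,
                        ["a_760", "b_760"])
        with pytest.raises(ParameterError):
            mbll(b, [760.0, 760.0])

    def test_nonpositive_intensity(self):
        b = SignalBlock("fnirs_intensity", np.zeros((2, 50)), 10.0,
                        ["a", "b"])
        with pytest.raises(InputError):
            mbll(b, [760.0, 850.0])


class TestWavelet:
    def test_perfect_reconstruction_without_threshold(self, rng):
        x = rng.standard_normal(512)
        coeffs = _wavelet.wavedec(x, "db4", 4)
        np.testing.assert_allclose(_wavelet.waverec(coeffs, "db4"), x,
                                   atol=1e-10)

    def test_spike_suppressed_sine_kept(self, rng):
        """Low-frequency sine + spikes riding on background noise: the MAD
        noise estimate sets the universal threshold, which removes the
        spikes (>= 80%) while the sine, living in the approximation
        coefficients, keeps its RMS within 5%."""
        rate, dur = 10.0, 60.0
        t = np.arange(int(rate * dur)) / rate
        sine = np.sin(2 * np.pi * 0.2 * t)
        noise = 0.6 * rng.standard_normal(len(t))
        spikes = np.zeros_like(sine)
        idx = rng.choice(len(sine), 12, replace=False)
        spikes[idx] = 2.8
        b = make_block(sine + noise + spikes, rate=rate, modality="fnirs_hb",
                       labels=["a"], chromophore=["HbO"])
        out = wavelet_denoise(b, "db4", 4)
        resid_spikes = np.abs(out.data[0][idx] - sine[idx])
        assert np.mean(resid_spikes) <= 0.2 * 2.8  # >= 80% spike reduction
        clean_mask = np.ones(len(sine), bool)
        for i in idx:  # exclude spike neighborhoods when scoring the sine
            clean_mask[max(0, i - 5):i + 6] = False
        rms_in = np.sqrt(np.mean(sine[clean_mask] ** 2))
        rms_out = np.sqrt(np.mean(out.data[0][clean_mask] ** 2))
        assert abs(rms_out / rms_in - 1) < 0.05

    def test_zero_in_zero_out(self):
        b = make_block(np.zeros(256))
        np.testing.assert_array_equal(wavelet_denoise(b).data, 0.0)

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            wavelet_denoise(make_block(np.zeros(8)), levels=4)


class TestSplineCorrect:
    def test_clean_sine_unchanged(self):
        b = make_block(_sine(0.4, rate=10.0, dur=120.0), rate=10.0)
        out = spline_correct(b, z_threshold=3.0)
        np.testing.assert_array_equal(out.data, b.data)

    def test_baseline_jump_corrected(self):
        rate, dur = 10.0, 120.0
        t = np.arange(int(rate * dur)) / rate
        clean = np.sin(2 * np.pi * 0.4 * t)
        jump = np.where((t >= 60.0) & (t < 63.0), 8.0, 0.0)
        b = make_block(clean + jump, rate=rate)
        out = spline_correct(b, z_threshold=3.0)
        err_before = np.sqrt(np.mean((b.data[0] - clean) ** 2))
        err_after = np.sqrt(np.mean((out.data[0] - clean) ** 2))
        assert err_after <= 0.3 * err_before  # >= 70% RMS error reduction

    def test_zero_threshold_rejected(self):
        with pytest.raises(ParameterError):
            spline_correct(make_block(np.zeros(100)), z_threshold=0.0)

    def test_idempotent_on_own_output(self):
        rate = 10.0
        t = np.arange(int(rate * 120)) / rate
        x = np.sin(2 * np.pi * 0.4 * t)
        x[600:630] += 8.0
        once = spline_correct(make_block(x, rate=rate), 3.0)
        twice = spline_correct(once, 3.0)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-9)


class TestRPeaks:
    def test_regular_train(self):
        """RR = 0.8 s over 10 s: 12 +/- 1 peaks, each within 20 ms of truth."""
        from neurofuse.simulate import sim_ecg
        ecg, gt = sim_ecg(10.0, 250.0, mean_rr_ms=800.0, lf_amp_ms=0.0,
                          hf_amp_ms=0.0, jitter_ms=0.0, seed=0)
        peaks = detect_r_peaks(ecg)
        assert abs(len(peaks) - 12) <= 1
        for p in peaks / ecg.rate:
            assert np.min(np.abs(gt.r_peak_times_s - p)) < 0.02

    def test_flat_signal_rejected(self):
        b = make_block(np.zeros(1000), modality="ecg")
        with pytest.raises(DetectionError):
            detect_r_peaks(b)

    def test_scale_invariance(self):
        from neurofuse.simulate import sim_ecg
        ecg, _ = sim_ecg(20.0, 250.0, seed=1)
        p1 = detect_r_peaks(ecg)
        p2 = detect_r_peaks(ecg.copy(data=ecg.data * 0.1))
        np.testing.assert_array_equal(p1, p2)


class TestAutoPipelines:
    def test_eeg_profile_step_order(self, rng):
        from neurofuse.simulate import sim_eeg
        eeg = sim_eeg(6, 20.0, 250.0, seed=0)
        eog = make_block(rng.standard_normal(eeg.n_samples), modality="eog")
        out, report = run_auto_pipeline(eeg, "eeg", eog=eog, seed=0)
        assert report.step_names == ["bandpass_2_50", "notch_60",
                                     "eog_regression", "ica_clean",
                                     "average_reference"]
        assert np.max(np.abs(out.data.sum(axis=0))) < 1e-6

    def test_fnirs_profile_type_transition(self, rng):
        inten = SignalBlock(
            "fnirs_intensity",
            1.0 + 0.01 * rng.standard_normal((2, 1200)), 10.0,
            ["a_760", "a_850"])
        out, report = run_auto_pipeline(inten, "fnirs")
        assert out.modality == "fnirs_hb"
        assert out.chromophore == ["HbO", "HbR"]
        assert report.step_names[0] == "mbll"

    def test_emg_nyquist_clipping(self, rng):
        emg = make_block(rng.standard_normal((1, 5000)), rate=500.0,
                         modality="emg")
        out, report = run_auto_pipeline(emg, "emg")
        bp = report.steps[0]
        assert bp["step"].startswith("bandpass_20_")
        upper = float(bp["step"].rsplit("_", 1)[1])
        assert upper < 250.0  # clipped below Nyquist
        assert out.n_channels == 2 and out.labels[1].endswith("_env")

    def test_ecg_profile_annotates_events(self):
        from neurofuse.simulate import sim_ecg
        ecg, gt = sim_ecg(30.0, 250.0, seed=2)
        out, report = run_auto_pipeline(ecg, "ecg")
        assert report.events is not None
        assert abs(len(report.events) - len(gt.r_peak_times_s)) <= 1
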