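"""Ground-truth signal generators for validation and debugging.

Every generator is a pure function of its parameters and a seed: the same
call regenerates bit-identical data.  Each returns, alongside the signals,
a :class:`GroundTruth` record of what was injected (coupling strengths,
shared-drive frequency and SNR, the exact RR series, class patterns), so
estimator tests can score recovery against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import coupling as cpl
from . import features as feat
from .containers import EpochSet, SignalBlock
from .errors import ParameterError

#: Band-power windowing shared by the fNIRS forward model and the NVC
#: estimator tests: a 2 s window stepped at the fNIRS sample period.
NVC_POWER_WINDOW_S = 2.0


@dataclass
class GroundTruth:
    """What the simulator injected, for recovery scoring."""

    seed: int
    nvc_strength: float | None = None
    cmc_drive_freq: float | None = None
    cmc_drive_snr: float | None = None
    rr_series_ms: np.ndarray | None = None
    r_peak_times_s: np.ndarray | None = None
    class_patterns: dict | None = None
    mixing: np.ndarray | None = None
    params: dict = field(default_factory=dict)


def _one_over_f(n: int, rate: float, exponent: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with power spectrum proportional to f^-exponent."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _band_noise(n: int, rate: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise band-limited to ``band`` (FFT brick wall)."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    spec = np.zeros(freqs.size, dtype=complex)
    m = (freqs >= band[0]) & (freqs <= band[1])
    spec[m] = np.exp(1j * rng.uniform(0, 2 * np.pi, int(m.sum())))
    x = np.fft.irfft(spec, n)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def sim_eeg(channels: int = 4, duration_s: float = 60.0, rate: float = 250.0,
            band_amplitudes: dict | None = None, noise_exponent: float = 1.0,
            noise_amplitude: float = 1.0, seed: int = 0) -> SignalBlock:
    """Synthetic EEG: band-limited oscillations plus 1/f^chi background.

    ``band_amplitudes`` maps a canonical band name or an explicit
    ``(low, high)`` tuple to an RMS amplitude in uV.  Defaults emulate a
    resting posterior rhythm (alpha 10 uV over a 1/f background).
    """
    if rate <= 0:
        raise ParameterError("rate must be positive")
    if band_amplitudes is None:
        band_amplitudes = {"alpha": 10.0}
    scheme = feat.band_scheme(rate)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    data = np.zeros((channels, n))
    for ch in range(channels):
        for band, amp in band_amplitudes.items():
            edges = scheme[band] if isinstance(band, str) else tuple(band)
            if edges[1] > rate / 2.0:
                raise ParameterError(
                    f"band {band} exceeds Nyquist at rate {rate}")
            data[ch] += amp * _band_noise(n, rate, edges, rng)
        if noise_amplitude > 0:
            data[ch] += noise_amplitude * _one_over_f(n, rate,
                                                      noise_exponent, rng)
    labels = [f"EEG{i + 1:02d}" for i in range(channels)]
    return SignalBlock("eeg", data, rate, labels, stage="raw")


def nvc_power(eeg: SignalBlock, band=cpl.NVC_DEFAULT_BAND,
              fnirs_rate: float = 10.0, channel: int = 0) -> SignalBlock:
    """The band-power time course both the forward model and the estimator
    use: window :data:`NVC_POWER_WINDOW_S`, step = one fNIRS sample."""
    tc = feat.band_power_timecourse(eeg, band, NVC_POWER_WINDOW_S,
                                    1.0 / fnirs_rate)
    return SignalBlock("aux", tc.data[channel:channel + 1], tc.rate,
                       [tc.labels[channel]], start_time=tc.start_time)


def sim_coupled_fnirs(eeg: SignalBlock, band=cpl.NVC_DEFAULT_BAND,
                      hrf: cpl.HRFParams | None = None,
                      coupling: float = 0.8, fnirs_rate: float = 10.0,
                      seed: int = 0):
    """Generate HbO/HbR with a known neurovascular coupling strength.

    HbO is the standardized HRF-convolved EEG band power plus Gaussian
    noise with variance ``1/coupling**2 - 1`` so the population correlation
    equals ``coupling``; HbR is ``-0.3 * HbO`` plus independent noise.
    Returns ``(fnirs_hb block, GroundTruth)``.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ParameterError("coupling must lie in [0, 1]")
    hrf = hrf or cpl.HRFParams()
    rng = np.random.default_rng(seed)
    power = nvc_power(eeg, band, fnirs_rate)
    predictor = cpl.hrf_predictor(power.data[0], hrf, rate=fnirs_rate)
    z = (predictor - predictor.mean()) / predictor.std()
    if coupling == 0.0:
        hbo = rng.standard_normal(z.size)
    elif coupling == 1.0:
        hbo = z.copy()
    else:
        sigma = np.sqrt(1.0 / coupling ** 2 - 1.0)
        hbo = z + sigma * rng.standard_normal(z.size)
    hbr = -0.3 * hbo + 0.2 * rng.standard_normal(z.size)
    block = SignalBlock("fnirs_hb", np.vstack([hbo, hbr]), fnirs_rate,
                        ["S1-D1_HbO", "S1-D1_HbR"],
                        chromophore=["HbO", "HbR"],
                        start_time=power.start_time, stage="raw")
    gt = GroundTruth(seed=seed, nvc_strength=coupling,
                     params={"band": list(band),
                             "window_s": NVC_POWER_WINDOW_S,
                             "fnirs_rate": fnirs_rate,
                             "hrf": vars(hrf)})
    return block, gt


def sim_emg_with_drive(eeg: SignalBlock | None = None,
                       drive_freq: float = 20.0, drive_snr: float = 1.0,
                       duration_s: float = 120.0, rate: float = 500.0,
                       seed: int = 0):
    """EEG/EMG pair sharing a narrowband drive at a known frequency and SNR.

    The common drive (2 Hz-wide noise centered on ``drive_freq``) is added
    to both signals.  ``drive_snr`` is the *in-band* power ratio: within
    the drive band, drive power equals ``drive_snr`` times each signal's
    own background power there, so the expected squared coherence at the
    drive frequency is ``(snr / (1 + snr))**2``.
    Returns ``(emg block, eeg block, GroundTruth)``.
    """
    if drive_snr <= 0:
        raise ParameterError("drive SNR must be positive")
    if drive_freq >= rate / 2.0:
        raise ParameterError("drive frequency must be below Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    band = (max(drive_freq - 1.0, 0.1), drive_freq + 1.0)
    drive = _band_noise(n, rate, band, rng)

    def band_var(x):
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(n, 1.0 / rate)
        m = (freqs >= band[0]) & (freqs <= band[1])
        return np.sum(np.abs(spec[m]) ** 2) / (n * n / 2.0)

    if eeg is None:
        eeg_bg = _one_over_f(n, rate, 1.0, rng)
    else:
        if eeg.rate != rate or eeg.n_samples != n:
            raise ParameterError("provided EEG must match duration and rate")
        eeg_bg = eeg.data[0]
    emg_bg = rng.standard_normal(n)  # broadband muscle background
    amp_eeg = np.sqrt(drive_snr * band_var(eeg_bg))
    amp_emg = np.sqrt(drive_snr * band_var(emg_bg))
    if eeg is None:
        eeg = SignalBlock("eeg", (eeg_bg + amp_eeg * drive)[None, :], rate,
                          ["C3"], stage="raw")
    else:
        eeg = eeg.copy(data=eeg.data + amp_eeg * drive[None, :])
    emg_data = emg_bg + amp_emg * drive
    emg = SignalBlock("emg", emg_data[None, :], rate, ["EMG1"], stage="raw")
    gt = GroundTruth(seed=seed, cmc_drive_freq=drive_freq,
                     cmc_drive_snr=drive_snr,
                     params={"duration_s": duration_s, "rate": rate})
    return emg, eeg, gt


def _qrs_template(rate: float, width_s: float = 0.02) -> np.ndarray:
    """Mexican-hat pulse standing in for a QRS complex."""
    half = int(round(5 * width_s * rate))
    t = np.arange(-half, half + 1) / rate
    s = width_s
    return (1 - (t / s) ** 2) * np.exp(-t ** 2 / (2 * s ** 2))


def sim_ecg(duration_s: float = 120.0, rate: float = 250.0,
            mean_rr_ms: float = 800.0, lf_amp_ms: float = 20.0,
            hf_amp_ms: float = 20.0, jitter_ms: float = 3.0, seed: int = 0):
    """Synthetic single-channel ECG with structured RR variability.

    The RR series is ``mean + LF sin(2 pi 0.1 t) + HF sin(2 pi 0.25 t) +
    jitter``; QRS template pulses are placed at the cumulative RR times.
    Returns ``(ecg block, GroundTruth)`` with the exact RR series and peak
    times recorded.
    """
    if not 300.0 <= mean_rr_ms <= 2000.0:
        raise ParameterError("mean RR must be within [300, 2000] ms")
    rng = np.random.default_rng(seed)
    n_beats = int(duration_s * 1000.0 / mean_rr_ms) + 10
    t_beat = np.arange(n_beats) * mean_rr_ms / 1000.0
    rr = (mean_rr_ms
          + lf_amp_ms * np.sin(2 * np.pi * 0.1 * t_beat)
          + hf_amp_ms * np.sin(2 * np.pi * 0.25 * t_beat)
          + jitter_ms * rng.standard_normal(n_beats))
    peak_times = np.cumsum(rr) / 1000.0
    peak_times = peak_times[peak_times < duration_s - 0.1]
    n = int(round(duration_s * rate))
    x = 0.02 * rng.standard_normal(n)  # measurement noise floor
    tpl = _qrs_template(rate)
    half = len(tpl) // 2
    for pt in peak_times:
        idx = int(round(pt * rate))
        lo, hi = idx - half, idx + half + 1
        s0, s1 = max(0, lo), min(n, hi)
        x[s0:s1] += tpl[s0 - lo: len(tpl) - (hi - s1)]
    ecg = SignalBlock("ecg", x[None, :] * 1000.0, rate, ["ECG"], stage="raw")
    gt = GroundTruth(seed=seed, rr_series_ms=rr[:peak_times.size],
                     r_peak_times_s=peak_times,
                     params={"mean_rr_ms": mean_rr_ms, "lf_amp_ms": lf_amp_ms,
                             "hf_amp_ms": hf_amp_ms, "jitter_ms": jitter_ms})
    return ecg, gt


def _hrf_bump(n: int, rate: float) -> np.ndarray:
    """Unit-peak hemodynamic bump spanning the epoch."""
    kernel = cpl.canonical_hrf(cpl.HRFParams(duration=max(n / rate, 1.0),
                                             rate=rate))
    out = np.zeros(n)
    out[:kernel.size] = kernel[:n]
    return out


def sim_mi_dataset(trials_per_class: int = 40, channels: int = 8,
                   rate: float = 100.0, epoch_s: float = 4.0,
                   effect_size: float = 2.0, seed: int = 0,
                   fnirs_channels: int = 4, fnirs_rate: float = 10.0):
    """Two-class motor-imagery-style multimodal dataset.

    EEG epochs are band-limited source signals mixed through a random
    orthonormal matrix; the first two sources have class-dependent variance
    (multiplied by ``1 + effect_size`` for one class and divided for the
    other, in opposite directions), which CSP can recover.  Hemoglobin
    epochs carry an HRF-shaped response whose amplitude is lateralized by
    class in proportion to ``effect_size``.  ``effect_size = 0`` produces
    exchangeable classes (chance-level decodable).

    Returns ``(EpochSet eeg, EpochSet fnirs_hb, GroundTruth)``.
    """
    if trials_per_class < 2:
        raise ParameterError("need at least 2 trials per class")
    if channels < 4:
        raise ParameterError("need at least 4 channels")
    if effect_size < 0:
        raise ParameterError("effect_size must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(epoch_s * rate))
    n_trials = 2 * trials_per_class
    labels = ["left"] * trials_per_class + ["right"] * trials_per_class
    order = rng.permutation(n_trials)
    labels = [labels[i] for i in order]

    gain = 1.0 + effect_size
    mixing, _ = np.linalg.qr(rng.standard_normal((channels, channels)))
    src_scale = {"left": np.ones(channels), "right": np.ones(channels)}
    src_scale["left"][0], src_scale["right"][0] = gain, 1.0 / gain
    src_scale["left"][1], src_scale["right"][1] = 1.0 / gain, gain

    eeg_epochs = np.empty((n_trials, channels, n))
    for t, lab in enumerate(labels):
        sources = np.vstack([_band_noise(n, rate, (8.0, 30.0), rng)
                             for _ in range(channels)])
        sources *= src_scale[lab][:, None]
        eeg_epochs[t] = mixing @ sources

    nf = int(round(epoch_s * fnirs_rate))
    bump = _hrf_bump(nf, fnirs_rate)
    amp = {"left": np.ones(fnirs_channels), "right": np.ones(fnirs_channels)}
    half_ch = fnirs_channels // 2
    amp["left"][:half_ch] += effect_size
    amp["right"][half_ch:] += effect_size
    fnirs_epochs = np.empty((n_trials, fnirs_channels, nf))
    for t, lab in enumerate(labels):
        resp = amp[lab][:, None] * bump[None, :]
        fnirs_epochs[t] = resp + 0.3 * rng.standard_normal((fnirs_channels,
                                                            nf))

    eeg = EpochSet(eeg_epochs, labels, 0.0, epoch_s, rate, "eeg",
                   ch_names=[f"EEG{i + 1:02d}" for i in range(channels)])
    fnirs = EpochSet(fnirs_epochs, labels, 0.0, epoch_s, fnirs_rate,
                     "fnirs_hb",
                     ch_names=[f"S{i + 1}-D{i + 1}_HbO"
                               for i in range(fnirs_channels)])
    gt = GroundTruth(seed=seed, mixing=mixing,
                     class_patterns={"left": src_scale["left"],
                                     "right": src_scale["right"],
                                     "fnirs_left": amp["left"],
                                     "fnirs_right": amp["right"]},
                     params={"effect_size": effect_size,
                             "trials_per_class": trials_per_class})
    return eeg, fnirs, gt
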