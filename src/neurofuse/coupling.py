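"""Dynamic brain-body coupling: NVC, CMC, HBI, and condition comparison.

Neurovascular coupling (NVC) is quantified as the absolute Pearson
correlation between an EEG band-power time course convolved with a
canonical double-gamma hemodynamic response function (HRF) and a measured
hemoglobin series, so values live in [0, 1].  Corticomuscular coherence
(CMC) is Welch magnitude-squared coherence between EEG and EMG with the
exact L-segment significance threshold ``1 - p**(1/(L-1))``.  Heart-brain
interaction (HBI) is a signed sliding-window correlation between EEG band
power and instantaneous heart rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps, stats

from .containers import SignalBlock
from .errors import InputError, NumericalError, ParameterError

#: Default band for NVC band-power extraction (alpha + beta), Hz.
NVC_DEFAULT_BAND = (8.0, 30.0)


@dataclass
class HRFParams:
    """Double-gamma HRF parameters (shapes unitless, scales in seconds).

    The canonical kernel peaks near ``(a1 - 1) * b1`` seconds (~5 s for the
    defaults) with an undershoot around ``(a2 - 1) * b2`` (~15 s) scaled by
    ``undershoot_ratio``.
    """

    peak_shape: float = 6.0        # a1
    peak_scale: float = 1.0        # b1 (s)
    undershoot_shape: float = 16.0  # a2
    undershoot_scale: float = 1.0   # b2 (s)
    undershoot_ratio: float = 1.0 / 6.0  # c
    duration: float = 32.0         # kernel length (s)
    rate: float = 10.0             # Hz

    def validate(self) -> None:
        vals = [self.peak_shape, self.peak_scale, self.undershoot_shape,
                self.undershoot_scale, self.undershoot_ratio, self.duration,
                self.rate]
        if any(not (np.isfinite(v) and v > 0) for v in vals):
            raise ParameterError("all HRF parameters must be positive")
        if self.duration * self.rate < 8:
            raise ParameterError("HRF kernel must span at least 8 samples")

    @property
    def peak_time(self) -> float:
        return (self.peak_shape - 1.0) * self.peak_scale


@dataclass
class CouplingResult:
    """Windowed coupling values for one channel pair plus a summary."""

    method: str
    pair: tuple[str, str]
    window_s: float
    step_s: float
    series: np.ndarray
    summary: float
    params: dict = field(default_factory=dict)
    threshold: float | None = None
    frequencies: np.ndarray | None = None
    spectrum: np.ndarray | None = None


def canonical_hrf(params: HRFParams | None = None) -> np.ndarray:
    """Sampled double-gamma HRF kernel, rescaled to unit peak.

    ``h(t) = g(t; a1, b1) - c * g(t; a2, b2)`` with ``g`` the gamma density.
    """
    params = params or HRFParams()
    params.validate()
    t = np.arange(0.0, params.duration, 1.0 / params.rate)
    g1 = stats.gamma.pdf(t, params.peak_shape, scale=params.peak_scale)
    g2 = stats.gamma.pdf(t, params.undershoot_shape,
                         scale=params.undershoot_scale)
    h = g1 - params.undershoot_ratio * g2
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ParameterError("degenerate HRF (identically zero)")
    return h / np.max(h)


def hrf_predictor(power: np.ndarray, hrf: HRFParams | None = None,
                  rate: float | None = None) -> np.ndarray:
    """Causally convolve a band-power series with the HRF kernel.

    The kernel is sampled at ``rate`` (default: the HRFParams rate); the
    full convolution is truncated to the input length.  The power series is
    demeaned first (the usual GLM-regressor convention), which keeps the
    resulting correlation exactly invariant to affine rescaling of the
    input and avoids a kernel ramp-in artifact from the DC level.
    """
    hrf = hrf or HRFParams()
    if rate is not None and rate != hrf.rate:
        hrf = HRFParams(hrf.peak_shape, hrf.peak_scale, hrf.undershoot_shape,
                        hrf.undershoot_scale, hrf.undershoot_ratio,
                        hrf.duration, rate)
    kernel = canonical_hrf(hrf)
    x = np.asarray(power, float).ravel()
    return np.convolve(x - x.mean(), kernel)[:len(x)]


def _abs_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise NumericalError("zero-variance input: correlation undefined")
    return float(abs(np.corrcoef(x, y)[0, 1]))


def nvc_static(eeg_power: SignalBlock, hb: SignalBlock,
               hrf: HRFParams | None = None, *, channel: int = 0,
               hb_channel: int = 0) -> CouplingResult:
    """Static NVC: |r| between HRF-convolved band power and hemoglobin."""
    if eeg_power.rate != hb.rate:
        raise InputError("resample both inputs to a common rate first")
    n = min(eeg_power.n_samples, hb.n_samples)
    if n < 8:
        raise InputError("inputs too short for NVC")
    power = eeg_power.data[channel, :n]
    target = hb.data[hb_channel, :n]
    predictor = hrf_predictor(power, hrf, rate=eeg_power.rate)
    r = _abs_corr(predictor, target)
    return CouplingResult(
        method="nvc", pair=(eeg_power.labels[channel], hb.labels[hb_channel]),
        window_s=n / eeg_power.rate, step_s=n / eeg_power.rate,
        series=np.array([]), summary=r,
        params={"hrf": vars(hrf or HRFParams()), "rate": eeg_power.rate})


def nvc_dynamic(eeg_power: SignalBlock, hb: SignalBlock,
                hrf: HRFParams | None = None, window_s: float = 60.0,
                step_s: float = 10.0, *, channel: int = 0,
                hb_channel: int = 0) -> CouplingResult:
    """Sliding-window NVC; summary is the mean of the window series."""
    hrf_p = hrf or HRFParams()
    hrf_p.validate()
    if window_s < 3.0 * hrf_p.peak_time:
        raise ParameterError(
            f"window_s must be >= 3x the HRF peak time "
            f"({3 * hrf_p.peak_time:.1f} s)")
    if step_s > window_s:
        raise ParameterError("step_s must not exceed window_s")
    if eeg_power.rate != hb.rate:
        raise InputError("resample both inputs to a common rate first")
    n = min(eeg_power.n_samples, hb.n_samples)
    power = eeg_power.data[channel, :n]
    target = hb.data[hb_channel, :n]
    predictor = hrf_predictor(power, hrf_p, rate=eeg_power.rate)
    win = int(round(window_s * eeg_power.rate))
    step = int(round(step_s * eeg_power.rate))
    n_win = (n - win) // step + 1
    if n_win < 2:
        raise ParameterError("need at least 2 windows; shorten window_s")
    series = np.empty(n_win)
    for w in range(n_win):
        sl = slice(w * step, w * step + win)
        series[w] = _abs_corr(predictor[sl], target[sl])
    return CouplingResult(
        method="nvc", pair=(eeg_power.labels[channel], hb.labels[hb_channel]),
        window_s=window_s, step_s=step_s, series=series,
        summary=float(np.mean(series)),
        params={"hrf": vars(hrf_p), "rate": eeg_power.rate})


def cmc(eeg: SignalBlock, emg: SignalBlock, band: tuple[float, float],
        segment_s: float = 2.0, *, channel: int = 0, emg_channel: int = 0,
        p: float = 0.05) -> CouplingResult:
    """Corticomuscular coherence with the exact L-segment threshold.

    Magnitude-squared coherence via Welch with L non-overlapping Hann
    segments; an independent-signals bin exceeds the attached threshold
    ``1 - p**(1/(L-1))`` with probability ``p``.
    """
    if eeg.rate != emg.rate:
        raise InputError("EEG and EMG must share a sampling rate")
    n = min(eeg.n_samples, emg.n_samples)
    nper = int(round(segment_s * eeg.rate))
    L = n // nper
    if L < 2:
        raise ParameterError("need at least 2 segments")
    if n < 10 * nper:
        raise ParameterError("duration must be >= 10 segments for stable CMC")
    f, coh = sps.coherence(eeg.data[channel, :n], emg.data[emg_channel, :n],
                           fs=eeg.rate, window="hann", nperseg=nper,
                           noverlap=0)
    lo, hi = band
    m = (f >= lo) & (f <= hi)
    if not m.any():
        raise ParameterError("band contains no frequency bins")
    threshold = 1.0 - p ** (1.0 / (L - 1))
    return CouplingResult(
        method="cmc", pair=(eeg.labels[channel], emg.labels[emg_channel]),
        window_s=segment_s, step_s=segment_s, series=coh[m],
        summary=float(np.max(coh[m])), threshold=float(threshold),
        frequencies=f, spectrum=coh,
        params={"segments": int(L), "p": p, "band": list(band)})


def cmc_threshold(L: int, p: float = 0.05) -> float:
    """Analytic coherence significance level for L independent segments."""
    if L < 2:
        raise ParameterError("need at least 2 segments")
    return 1.0 - p ** (1.0 / (L - 1))


def hbi(eeg_power: SignalBlock, hr: np.ndarray, window_s: float = 30.0,
        step_s: float = 5.0, *, channel: int = 0) -> CouplingResult:
    """Heart-brain interaction: sliding signed correlation between EEG band
    power and instantaneous heart rate (already interpolated to the power
    rate).  Zero-variance windows are NaN, not zero; the summary is the
    mean absolute correlation over defined windows.
    """
    hr = np.asarray(hr, dtype=float).ravel()
    n = min(eeg_power.n_samples, hr.size)
    if n < 8:
        raise InputError("inputs too short for HBI")
    win = int(round(window_s * eeg_power.rate))
    step = int(round(step_s * eeg_power.rate))
    if win > n:
        raise ParameterError("window longer than the data")
    power = eeg_power.data[channel, :n]
    n_win = (n - win) // step + 1
    series = np.empty(n_win)
    for w in range(n_win):
        sl = slice(w * step, w * step + win)
        pw, hw = power[sl], hr[sl]
        if np.std(pw) == 0 or np.std(hw) == 0:
            series[w] = np.nan
        else:
            series[w] = np.corrcoef(pw, hw)[0, 1]
    if np.all(np.isnan(series)):
        raise NumericalError("every HBI window has zero variance")
    return CouplingResult(
        method="hbi", pair=(eeg_power.labels[channel], "heart_rate"),
        window_s=window_s, step_s=step_s, series=series,
        summary=float(np.nanmean(np.abs(series))),
        params={"rate": eeg_power.rate})


def instantaneous_hr(peak_times_s: np.ndarray, out_times_s: np.ndarray
                     ) -> np.ndarray:
    """Beats-per-minute series from R-peak times, linearly interpolated."""
    peak_times_s = np.asarray(peak_times_s, dtype=float)
    if peak_times_s.size < 3:
        raise InputError("need at least 3 R peaks")
    rr = np.diff(peak_times_s)
    mid = peak_times_s[:-1] + rr / 2.0
    return np.interp(out_times_s, mid, 60.0 / rr)


def compare_conditions(values_a, values_b, *, alpha: float = 0.05,
                       correction: str = "holm"):
    """Paired two-tailed t-tests per channel with multiplicity correction.

    ``values_a`` / ``values_b`` are samples x channels (or 1-D for a single
    channel).  Returns ``(t statistics, raw p-values, corrected decisions)``
    where decisions are booleans at family-wise/FDR level ``alpha`` using
    the Holm or Benjamini-Hochberg procedure.
    """
    from statsmodels.stats.multitest import multipletests

    a = np.atleast_2d(np.asarray(values_a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(values_b, dtype=float).T).T
    if a.shape != b.shape:
        raise InputError("paired samples must have equal shapes")
    if a.shape[0] < 3:
        raise InputError("need at least 3 paired observations")
    diffs = a - b
    if np.allclose(diffs.std(axis=0, ddof=1), 0.0):
        raise NumericalError("zero-variance differences: t-test degenerate")
    t, p = stats.ttest_rel(a, b, axis=0)
    method = {"holm": "holm", "bh": "fdr_bh", "fdr_bh": "fdr_bh"}.get(correction)
    if method is None:
        raise ParameterError("correction must be 'holm' or 'bh'")
    reject, *_ = multipletests(np.atleast_1d(p), alpha=alpha, method=method)
    return np.atleast_1d(t), np.atleast_1d(p), reject
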