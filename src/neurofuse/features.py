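"""Cross-domain feature engineering.

Spectral (Welch PSD, band power, band-power time courses, 1/f aperiodic
fit), time-domain (Hjorth & friends), nonlinear (sample entropy), cardiac
(HRV), muscular (nonnegative synergy factorization) and network
(coherence connectivity) features, all returned either as plain arrays or
as a :class:`FeatureSet` table with provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import SignalBlock
from .errors import InputError, NumericalError, ParameterError

#: Canonical EEG frequency bands in Hz.  The gamma upper edge is resolved
#: against the Nyquist frequency at use time.
CANONICAL_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, None),  # None -> min(100, 0.9 * Nyquist)
}


def band_scheme(rate: float) -> dict[str, tuple[float, float]]:
    """Resolve :data:`CANONICAL_BANDS` for a concrete sampling rate."""
    nyq = rate / 2.0
    out = {}
    for name, (lo, hi) in CANONICAL_BANDS.items():
        hi = min(100.0, 0.9 * nyq) if hi is None else hi
        if lo >= nyq:
            continue
        out[name] = (lo, min(hi, 0.999 * nyq))
    return out


@dataclass
class FeatureSet:
    """Observations x features table with names, units and provenance."""

    values: np.ndarray
    names: list[str]
    units: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.names):
            raise InputError("one name per feature column required")
        if self.units is None:
            self.units = [""] * len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


# ---------------------------------------------------------------------------
# Spectral


def welch_psd(block: SignalBlock, window_s: float = 2.0,
              overlap: float = 0.5):
    """One-sided Welch PSD (Hann window) per channel.

    Returns ``(frequencies, psd)`` with ``psd`` shaped channels x freqs; the
    integral of the PSD over frequency approximates the signal variance.
    """
    nper = int(round(window_s * block.rate))
    if nper < 8:
        raise ParameterError("window must span at least 8 samples")
    if nper > block.n_samples:
        raise ParameterError("window longer than the signal")
    if not 0 <= overlap < 1:
        raise ParameterError("overlap must be in [0, 1)")
    f, psd = sps.welch(block.data, fs=block.rate, window="hann",
                       nperseg=nper, noverlap=int(nper * overlap), axis=1,
                       detrend="constant")
    return f, psd


def band_power(block: SignalBlock, scheme=None, relative: bool = False,
               window_s: float = 2.0, overlap: float = 0.5) -> FeatureSet:
    """Per-channel power integrated over each named band."""
    scheme = scheme or band_scheme(block.rate)
    nyq = block.rate / 2.0
    for name, (lo, hi) in scheme.items():
        if hi > nyq:
            raise ParameterError(f"band {name} exceeds Nyquist ({nyq} Hz)")
    f, psd = welch_psd(block, window_s, overlap)
    total = np.trapezoid(psd[:, (f >= 0.5) & (f <= nyq)],
                         f[(f >= 0.5) & (f <= nyq)], axis=1)
    rows = []
    for ch in range(block.n_channels):
        row = []
        for name, (lo, hi) in scheme.items():
            m = (f >= lo) & (f <= hi)
            p = np.trapezoid(psd[ch, m], f[m])
            row.append(p / total[ch] if relative and total[ch] > 0 else p)
        rows.append(row)
    unit = "fraction" if relative else "uV^2"
    return FeatureSet(np.array(rows),
                      [f"{name}" for name in scheme],
                      units=[unit] * len(scheme),
                      provenance={"op": "band_power", "relative": relative,
                                  "scheme": {k: list(v)
                                             for k, v in scheme.items()},
                                  "channels": block.labels})


def band_power_timecourse(block: SignalBlock, band: tuple[float, float],
                          window_s: float, step_s: float) -> SignalBlock:
    """Sliding-window band power as a new signal at rate ``1/step_s``."""
    lo, hi = band
    if window_s < 2.0 / lo:
        raise ParameterError(
            f"window {window_s}s too short for band low edge {lo} Hz")
    if step_s > window_s:
        raise ParameterError("step_s must not exceed window_s")
    win = int(round(window_s * block.rate))
    step = int(round(step_s * block.rate))
    if win > block.n_samples:
        raise ParameterError("window longer than the signal")
    n_win = (block.n_samples - win) // step + 1
    # all windows at once: (channels, n_win, win) view, one periodogram call
    view = np.lib.stride_tricks.sliding_window_view(
        block.data, win, axis=1)[:, ::step, :][:, :n_win, :]
    f, psd = sps.periodogram(view, fs=block.rate, window="hann", axis=-1)
    m = (f >= lo) & (f <= hi)
    out = np.trapezoid(psd[..., m], f[m], axis=-1)
    return SignalBlock("aux", out, 1.0 / step_s,
                       [f"{l}_bp" for l in block.labels],
                       start_time=block.start_time + window_s / 2.0,
                       stage=block.stage)


def aperiodic_fit(frequencies, psd, fit_range=(1.0, 40.0)):
    """Fit ``log10 psd = offset - exponent * log10 f`` over ``fit_range``.

    Returns ``(offset, exponent)``.
    """
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(psd, dtype=float)
    m = (f >= fit_range[0]) & (f <= fit_range[1]) & (f > 0)
    if m.sum() < 5:
        raise ParameterError("need at least 5 frequency bins in fit range")
    if np.any(p[m] <= 0):
        raise InputError("PSD must be positive inside the fit range")
    slope, intercept = np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)
    return float(intercept), float(-slope)


# ---------------------------------------------------------------------------
# Time domain


def time_domain_features(block: SignalBlock) -> FeatureSet:
    """Mean, variance, RMS, zero-crossing rate and Hjorth parameters.

    Hjorth mobility is sqrt(var(dx)/var(x)); complexity is
    mobility(dx)/mobility(x).  Constant channels get NaN mobility and
    complexity (explicit missing markers).
    """
    if block.n_samples < 3:
        raise InputError("need at least 3 samples")
    rows = []
    for x in block.data:
        var = np.var(x)
        dx = np.diff(x)
        zcr = np.mean(np.diff(np.signbit(x)) != 0)
        if var == 0:
            mob, comp = np.nan, np.nan
        else:
            mob = np.sqrt(np.var(dx) / var)
            var_dx = np.var(dx)
            mob_dx = np.sqrt(np.var(np.diff(dx)) / var_dx) if var_dx > 0 \
                else np.nan
            comp = mob_dx / mob if mob > 0 else np.nan
        rows.append([np.mean(x), var, np.sqrt(np.mean(x ** 2)), zcr,
                     var, mob, comp])
    names = ["mean", "variance", "rms", "zero_crossing_rate",
             "hjorth_activity", "hjorth_mobility", "hjorth_complexity"]
    fs = FeatureSet.__new__(FeatureSet)
    fs.values = np.array(rows, dtype=float)
    fs.names = names
    fs.units = ["uV", "uV^2", "uV", "1/sample", "uV^2", "", ""]
    fs.provenance = {"op": "time_domain_features", "channels": block.labels}
    return fs


# ---------------------------------------------------------------------------
# Nonlinear


def sample_entropy(series, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy SampEn(m, r * SD), self-matches excluded.

    ``r`` is a tolerance expressed as a fraction of the series standard
    deviation (floored at 1e-12 so constant series stay defined).
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n <= m + 1:
        raise InputError(f"series of length {n} too short for m={m}")
    tol = max(r * np.std(x), 1e-12)
    b_trim = _count_matches(x, m, tol, n - m)
    a_trim = _count_matches(x, m + 1, tol, n - m)
    if b_trim == 0:
        raise NumericalError("no template matches at length m; entropy undefined")
    if a_trim == 0:
        return float("inf")
    return float(-np.log(a_trim / b_trim))


def _count_matches(x, mm, tol, n_templates):
    """Matched template pairs of length ``mm`` over ``n_templates`` templates.

    Both match counts use N - m templates (the standard convention), so the
    A/B ratio is a plain conditional probability.
    """
    if n_templates < 2:
        return 0
    emb = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_templates]
    dist = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=-1)
    within = dist <= tol
    np.fill_diagonal(within, False)
    return int(within.sum())


# ---------------------------------------------------------------------------
# Heart-rate variability


def hrv_metrics(rr_ms, *, alpha_warn=None) -> FeatureSet:
    """Time- and frequency-domain HRV statistics from RR intervals (ms).

    SDNN (n-1 denominator), RMSSD, pNN50 always; LF (0.04-0.15 Hz), HF
    (0.15-0.4 Hz) and LF/HF from a Lomb-Scargle periodogram of the RR
    tachogram when at least ~2 minutes of data are present (otherwise the
    spectral columns are NaN).
    """
    rr = np.asarray(rr_ms, dtype=float).ravel()
    if rr.size < 2:
        raise InputError("need at least 2 RR intervals")
    diffs = np.diff(rr)
    sdnn = float(np.std(rr, ddof=1)) if rr.size >= 2 else np.nan
    rmssd = float(np.sqrt(np.mean(diffs ** 2)))
    pnn50 = float(np.mean(np.abs(diffs) > 50.0))
    total_s = rr.sum() / 1000.0
    lf = hf = ratio = np.nan
    if total_s >= 120.0 and rr.size >= 10 and np.std(rr) > 0:
        t = np.cumsum(rr) / 1000.0
        y = rr - rr.mean()
        freqs = np.linspace(0.01, 0.5, 400)
        pgram = sps.lombscargle(t, y, 2 * np.pi * freqs, normalize=False)
        # convert to a density-like quantity; only band ratios matter
        pxx = pgram * 2.0 / rr.size
        lf_m = (freqs >= 0.04) & (freqs < 0.15)
        hf_m = (freqs >= 0.15) & (freqs <= 0.4)
        lf = float(np.trapezoid(pxx[lf_m], freqs[lf_m]))
        hf = float(np.trapezoid(pxx[hf_m], freqs[hf_m]))
        ratio = lf / hf if hf > 0 else np.nan
    values = [[sdnn, rmssd, pnn50, lf, hf, ratio]]
    fs = FeatureSet.__new__(FeatureSet)
    fs.values = np.array(values, dtype=float)
    fs.names = ["sdnn", "rmssd", "pnn50", "lf_power", "hf_power", "lf_hf"]
    fs.units = ["ms", "ms", "fraction", "ms^2", "ms^2", ""]
    fs.provenance = {"op": "hrv_metrics", "n_intervals": int(rr.size)}
    return fs


# ---------------------------------------------------------------------------
# EMG synergies


def emg_synergies(envelopes, k: int, seed: int = 0):
    """Nonnegative matrix factorization of muscle envelopes.

    Returns ``(W muscles x k, H k x samples, VAF)`` with
    ``VAF = 1 - |X - WH|^2 / |X|^2``.
    """
    from sklearn.decomposition import NMF

    X = np.asarray(envelopes, dtype=float)
    if X.ndim != 2:
        raise InputError("envelopes must be a muscles x samples matrix")
    if np.any(X < 0):
        raise InputError("envelopes must be nonnegative")
    if not 1 <= k <= X.shape[0]:
        raise ParameterError("k must be between 1 and the number of muscles")
    nmf = NMF(n_components=k, solver="mu", init="nndsvda", max_iter=2000,
              tol=1e-8, random_state=int(seed))
    W = nmf.fit_transform(X)
    H = nmf.components_
    resid = np.linalg.norm(X - W @ H) ** 2
    vaf = 1.0 - resid / np.linalg.norm(X) ** 2
    return W, H, float(vaf)


# ---------------------------------------------------------------------------
# Connectivity


def connectivity_matrix(block: SignalBlock, band: tuple[float, float],
                        window_s: float = 2.0) -> np.ndarray:
    """Band-averaged magnitude-squared coherence between every channel pair.

    Symmetric with unit diagonal, entries in [0, 1].
    """
    if block.n_channels < 2:
        raise InputError("connectivity needs at least 2 channels")
    lo, hi = band
    if not 0 <= lo < hi <= block.rate / 2.0:
        raise ParameterError("band must satisfy 0 <= low < high <= Nyquist")
    nper = min(int(round(window_s * block.rate)), block.n_samples)
    n = block.n_channels
    C = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            f, coh = sps.coherence(block.data[i], block.data[j],
                                   fs=block.rate, nperseg=nper)
            m = (f >= lo) & (f <= hi)
            C[i, j] = C[j, i] = float(np.clip(np.mean(coh[m]), 0.0, 1.0))
    return C
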