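"""Modality-specific signal cleaning: filters, artifact removal, MBLL, R peaks.

Each operation takes and returns :class:`~neurofuse.containers.SignalBlock`
objects.  :func:`run_auto_pipeline` chains the per-modality steps in a fixed
order and records what it did in a :class:`PipelineReport`.

Filter family is Butterworth (order 4 by default) applied forward-backward
for zero phase; the notch is an IIR notch with Q = 30.  These are the
conventional choices for biosignal work; cutoffs are arguments, not
constants.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal as sps, stats

from . import _wavelet
from .containers import EventTable, SignalBlock
from .errors import (AlignmentError, CorrectionError, DetectionError,
                     InputError, NumericalError, ParameterError)

logger = logging.getLogger(__name__)

#: Molar extinction coefficients in 1/(cm*mM) at the default NIRS
#: wavelengths, (epsilon_HbO, epsilon_HbR) per wavelength.  Values follow the
#: compilations commonly used in CW-NIRS processing software.
DEFAULT_EXTINCTION = {
    760.0: (1.4866, 3.8437),
    850.0: (2.5264, 1.7986),
}
DEFAULT_DPF = 6.0


@dataclass
class FilterSpec:
    """Frequency-selective filter description.

    ``kind`` is one of bandpass/highpass/lowpass/notch.  For a notch,
    ``low`` is the center frequency and ``high`` is ignored.
    """

    kind: str
    low: float | None = None
    high: float | None = None
    order: int = 4
    zero_phase: bool = True

    def validate(self, rate: float) -> None:
        nyq = rate / 2.0
        if self.kind not in ("bandpass", "highpass", "lowpass", "notch"):
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")
        if self.kind == "bandpass":
            if not (self.low is not None and self.high is not None
                    and 0 < self.low < self.high < nyq):
                raise ParameterError(
                    f"bandpass needs 0 < low < high < {nyq} Hz")
        elif self.kind == "highpass":
            if not (self.low is not None and 0 < self.low < nyq):
                raise ParameterError("highpass cutoff must be in (0, Nyquist)")
        elif self.kind == "lowpass":
            if not (self.high is not None and 0 < self.high < nyq):
                raise ParameterError("lowpass cutoff must be in (0, Nyquist)")
        elif self.kind == "notch":
            if not (self.low is not None and 0 < self.low < nyq):
                raise ParameterError("notch center must be below Nyquist")


@dataclass
class PipelineReport:
    """Ordered record of executed preprocessing steps."""

    profile: str = ""
    steps: list[dict] = field(default_factory=list)
    events: EventTable | None = None

    def add(self, name: str, params: dict, channels: list[str],
            var_before: float, var_after: float) -> None:
        self.steps.append({"step": name, "params": params,
                           "channels": list(channels),
                           "var_before": float(var_before),
                           "var_after": float(var_after)})

    @property
    def step_names(self) -> list[str]:
        return [s["step"] for s in self.steps]

    def to_json(self, path=None) -> str:
        payload = {"profile": self.profile, "steps": self.steps}
        text = json.dumps(payload, indent=1, default=str)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text


def filter_signal(block: SignalBlock, spec: FilterSpec) -> SignalBlock:
    """Apply ``spec`` to every channel (zero-phase by default)."""
    spec.validate(block.rate)
    if spec.kind == "notch":
        b, a = sps.iirnotch(spec.low, Q=30.0, fs=block.rate)
        if spec.zero_phase:
            out = sps.filtfilt(b, a, block.data, axis=1)
        else:
            out = sps.lfilter(b, a, block.data, axis=1)
        return block.copy(data=out)
    if spec.kind == "bandpass":
        wn, btype = [spec.low, spec.high], "bandpass"
    elif spec.kind == "highpass":
        wn, btype = spec.low, "highpass"
    else:
        wn, btype = spec.high, "lowpass"
    sos = sps.butter(spec.order, wn, btype=btype, fs=block.rate, output="sos")
    if spec.zero_phase:
        out = sps.sosfiltfilt(sos, block.data, axis=1)
    else:
        out = sps.sosfilt(sos, block.data, axis=1)
    return block.copy(data=out)


def eog_regress(eeg: SignalBlock, eog: SignalBlock) -> SignalBlock:
    """Remove ocular activity by least-squares regression on EOG channels.

    Each EEG channel's projection onto the span of the EOG channels is
    subtracted, leaving residuals orthogonal to every EOG channel.
    """
    if eeg.rate != eog.rate:
        raise AlignmentError("EEG and EOG sampling rates differ")
    if eeg.n_samples != eog.n_samples:
        raise AlignmentError("EEG and EOG lengths differ; align first")
    E = eog.data.T  # samples x eog-channels
    if not np.any(np.abs(E) > 0):
        return eeg.copy()
    Y = eeg.data.T
    coef, *_ = np.linalg.lstsq(E, Y, rcond=None)
    return eeg.copy(data=(Y - E @ coef).T)


def rereference_average(eeg: SignalBlock) -> SignalBlock:
    """Subtract the per-sample mean over channels (average reference)."""
    if eeg.n_channels < 2:
        raise InputError("average reference needs at least two channels")
    return eeg.copy(data=eeg.data - eeg.data.mean(axis=0, keepdims=True))


def ica_clean(eeg: SignalBlock, reference: SignalBlock | None = None, *,
              corr_threshold: float = 0.7, kurtosis_factor: float = 3.0,
              seed: int = 0):
    """ICA-based artifact rejection.

    Components correlating with a reference channel beyond
    ``corr_threshold`` in absolute value, or whose (Pearson) kurtosis
    exceeds ``kurtosis_factor`` times the median component kurtosis, are
    zeroed before reconstruction.  Deterministic for a fixed ``seed``.

    Returns ``(cleaned block, rejected component indices)``.
    """
    from sklearn.decomposition import FastICA

    if eeg.n_channels < 4:
        raise InputError("ICA cleaning needs at least 4 channels")
    if eeg.n_samples <= eeg.n_channels * 20:
        raise InputError("ICA cleaning needs > 20 samples per channel")
    X = eeg.data.T
    try:
        ica = FastICA(whiten="unit-variance", random_state=int(seed),
                      max_iter=1000, tol=1e-6)
        S = ica.fit_transform(X)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise NumericalError(
            "ICA decomposition failed (rank-deficient data?); consider "
            "dropping flat or duplicated channels") from exc
    kurt = stats.kurtosis(S, axis=0, fisher=False)
    reject = kurt > kurtosis_factor * np.median(kurt)
    if reference is not None:
        for ref_ch in reference.data:
            if np.std(ref_ch) == 0:
                continue
            for i in range(S.shape[1]):
                r = np.corrcoef(S[:, i], ref_ch)[0, 1]
                if abs(r) > corr_threshold:
                    reject[i] = True
    rejected = np.flatnonzero(reject)
    S_clean = S.copy()
    S_clean[:, rejected] = 0.0
    X_clean = ica.inverse_transform(S_clean)
    return eeg.copy(data=X_clean.T), rejected.tolist()


def mbll(intensity: SignalBlock, wavelengths, dpf=None, distance=3.0,
         extinction=None) -> SignalBlock:
    """Convert raw optical intensities to HbO/HbR via the modified
    Beer-Lambert law.

    Channels are consumed in consecutive two-wavelength pairs.  For each
    pair the optical-density change is ``-log10(I / mean(I))``; the 2x2
    extinction matrix at the pair's wavelengths is (pseudo)inverted and the
    OD changes, normalized by source-detector ``distance`` (cm) and the
    differential pathlength factor, map to concentration changes in uM.

    Parameters
    ----------
    wavelengths : sequence of float
        Per-channel wavelength in nm (length = channel count).
    dpf : float or mapping wavelength -> float
        Differential pathlength factor; default 6.0 for all wavelengths.
    distance : float or sequence
        Source-detector separation in cm, scalar or per pair.
    extinction : mapping wavelength -> (eps_HbO, eps_HbR), optional
        In 1/(cm*mM); defaults cover 760 and 850 nm.
    """
    if intensity.modality != "fnirs_intensity":
        raise InputError("mbll expects a raw fNIRS intensity block")
    if intensity.n_channels % 2:
        raise InputError("channels must form two-wavelength pairs")
    if np.any(intensity.data <= 0):
        raise InputError("intensities must be strictly positive")
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size != intensity.n_channels:
        raise ParameterError("need one wavelength per channel")
    ext = dict(DEFAULT_EXTINCTION)
    if extinction:
        ext.update({float(k): tuple(v) for k, v in extinction.items()})
    if dpf is None:
        dpf = DEFAULT_DPF
    dpf_of = (lambda w: float(dpf[w])) if isinstance(dpf, dict) \
        else (lambda w: float(dpf))
    n_pairs = intensity.n_channels // 2
    distances = np.broadcast_to(np.asarray(distance, dtype=float), (n_pairs,))

    od = -np.log10(intensity.data / intensity.data.mean(axis=1, keepdims=True))
    out = np.empty((2 * n_pairs, intensity.n_samples))
    labels, chromo = [], []
    for p in range(n_pairs):
        w1, w2 = wavelengths[2 * p], wavelengths[2 * p + 1]
        for w in (w1, w2):
            if w not in ext:
                raise ParameterError(
                    f"no extinction coefficients for {w} nm; pass extinction=")
        E = np.array([ext[w1], ext[w2]])  # rows: wavelengths; cols: HbO, HbR
        if abs(np.linalg.det(E)) < 1e-9:
            raise ParameterError(
                f"extinction matrix singular for pair ({w1}, {w2}) nm")
        d = distances[p]
        od_norm = np.vstack([od[2 * p] / (d * dpf_of(w1)),
                             od[2 * p + 1] / (d * dpf_of(w2))])
        conc_mM = np.linalg.pinv(E) @ od_norm
        out[2 * p:2 * p + 2] = conc_mM * 1000.0  # mM -> uM
        pair_name = intensity.labels[2 * p].rsplit("_", 1)[0]
        labels += [f"{pair_name}_HbO", f"{pair_name}_HbR"]
        chromo += ["HbO", "HbR"]
    return SignalBlock("fnirs_hb", out, intensity.rate, labels,
                       chromophore=chromo, start_time=intensity.start_time,
                       stage=intensity.stage)


def mbll_forward(hbo: np.ndarray, hbr: np.ndarray, baseline, wavelengths,
                 dpf=None, distance=3.0, extinction=None) -> np.ndarray:
    """Forward Beer-Lambert model: concentrations (uM) -> raw intensities.

    The exact inverse of :func:`mbll` up to the temporal-mean baseline;
    used by the simulator and the recovery tests.
    """
    ext = dict(DEFAULT_EXTINCTION)
    if extinction:
        ext.update({float(k): tuple(v) for k, v in extinction.items()})
    if dpf is None:
        dpf = DEFAULT_DPF
    dpf_of = (lambda w: float(dpf[w])) if isinstance(dpf, dict) \
        else (lambda w: float(dpf))
    w1, w2 = float(wavelengths[0]), float(wavelengths[1])
    E = np.array([ext[w1], ext[w2]])
    conc_mM = np.vstack([hbo, hbr]) / 1000.0
    od = E @ conc_mM
    od[0] *= distance * dpf_of(w1)
    od[1] *= distance * dpf_of(w2)
    base = np.broadcast_to(np.asarray(baseline, dtype=float)[:, None], od.shape)
    return base * 10.0 ** (-od)


def wavelet_denoise(block: SignalBlock, wavelet: str = "db4",
                    levels: int = 4) -> SignalBlock:
    """Per-channel wavelet shrinkage (soft universal threshold)."""
    if block.n_samples < 2 ** levels:
        raise InputError(
            f"{block.n_samples} samples cannot support {levels} DWT levels")
    out = np.vstack([_wavelet.denoise(ch, wavelet, levels)
                     for ch in block.data])
    return block.copy(data=out)


def _moving_std(x: np.ndarray, win: int) -> np.ndarray:
    """Centered moving standard deviation with edge replication."""
    pad = win // 2
    xp = np.pad(x, pad, mode="edge")
    c1 = np.cumsum(np.insert(xp, 0, 0.0))
    c2 = np.cumsum(np.insert(xp ** 2, 0, 0.0))
    n = win
    s1 = c1[n:] - c1[:-n]
    s2 = c2[n:] - c2[:-n]
    var = np.maximum(s2 / n - (s1 / n) ** 2, 0.0)
    return np.sqrt(var)[:x.size]


def spline_correct(block: SignalBlock, z_threshold: float = 3.0, *,
                   merge_gap_s: float = 5.0, knot_s: float = 1.0) -> SignalBlock:
    """Correct abnormal segments by subtracting a fitted cubic-spline baseline.

    A segment is abnormal where the 1 s moving standard deviation exceeds
    ``z_threshold`` times its median.  Flagged runs closer than
    ``merge_gap_s`` are merged (a plateau artifact only spikes the moving
    std at its two edges).  Within each segment a cubic spline baseline is
    fitted and its interior component (baseline minus the chord between its
    boundary values) subtracted, which enforces continuity at the edges.
    Artifact-free signals are returned unchanged.  Detection and correction
    are iterated to a fixpoint (residual edge transients from a corrected
    segment may themselves be flagged), which makes the operation
    idempotent.
    """
    if not z_threshold > 0:
        raise ParameterError("z_threshold must be > 0")
    win = max(int(round(block.rate)), 2)
    out = block.data.copy()
    for ci in range(block.n_channels):
        for _ in range(20):  # fixpoint iteration
            x = out[ci]
            mstd = _moving_std(x, win)
            med = np.median(mstd)
            if med == 0:
                break
            mask = mstd > z_threshold * med
            if not mask.any():
                break
            segments = _runs(mask)
            segments = [(max(0, i0 - win // 2), min(x.size, i1 + win // 2))
                        for i0, i1 in segments]
            merged = [segments[0]]
            gap = int(merge_gap_s * block.rate)
            for i0, i1 in segments[1:]:
                if i0 - merged[-1][1] < gap:
                    merged[-1] = (merged[-1][0], i1)
                else:
                    merged.append((i0, i1))
            if len(merged) == 1 and merged[0] == (0, x.size):
                raise CorrectionError(
                    "entire channel flagged as abnormal; inspect the data "
                    "or raise z_threshold")
            for i0, i1 in merged:
                out[ci, i0:i1] = _despike_segment(x[i0:i1], block.rate,
                                                  knot_s)
    return block.copy(data=out)


def _despike_segment(seg: np.ndarray, rate: float, knot_s: float
                     ) -> np.ndarray:
    """Subtract a cubic-spline baseline, keeping the segment edges fixed."""
    t = np.arange(seg.size, dtype=float)
    n_knots = max(int((seg.size / rate) / knot_s) - 1, 0)
    if n_knots >= 1:
        knots = np.linspace(t[0], t[-1], n_knots + 2)[1:-1]
        baseline = interpolate.LSQUnivariateSpline(t, seg, knots, k=3)(t)
    else:
        baseline = np.polyval(np.polyfit(t, seg, min(3, seg.size - 1)), t)
    chord = np.linspace(baseline[0], baseline[-1], seg.size)
    return seg - (baseline - chord)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(edges[::2], edges[1::2]))


def detect_r_peaks(ecg: SignalBlock) -> np.ndarray:
    """Locate R peaks: bandpass, differentiate, square, integrate, threshold.

    The adaptive threshold is proportional to the integrated signal's upper
    percentile, so detection is invariant to amplitude scaling.  A 200 ms
    refractory period suppresses double detections.
    """
    if ecg.n_channels != 1:
        raise InputError("R-peak detection expects a single-channel ECG")
    if ecg.rate < 100:
        raise InputError("R-peak detection needs rate >= 100 Hz")
    if ecg.duration < 2.0:
        raise InputError("R-peak detection needs >= 2 s of data")
    x = ecg.data[0]
    if np.ptp(x) == 0:
        raise DetectionError("flat ECG signal: no peaks found")
    filt = filter_signal(ecg, FilterSpec("bandpass", 5.0, 15.0, order=2)).data[0]
    deriv = np.gradient(filt)
    squared = deriv ** 2
    win = max(int(round(0.15 * ecg.rate)), 1)
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")
    thr = 0.3 * np.percentile(integrated, 99)
    refractory = int(round(0.2 * ecg.rate))
    cand, _ = sps.find_peaks(integrated, height=thr, distance=refractory)
    if cand.size == 0:
        raise DetectionError("no QRS complexes found")
    # refine each detection to the local extremum of the bandpassed ECG
    half = int(round(0.1 * ecg.rate))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        peaks.append(lo + int(np.argmax(np.abs(filt[lo:hi]))))
    peaks = np.unique(peaks)
    keep = [peaks[0]]
    for p in peaks[1:]:
        if p - keep[-1] >= refractory:
            keep.append(p)
    return np.asarray(keep)


# ---------------------------------------------------------------------------
# Automatic pipelines


def run_auto_pipeline(block: SignalBlock, profile: str, *,
                      eog: SignalBlock | None = None, line_freq: float = 60.0,
                      seed: int = 0, mbll_kwargs: dict | None = None):
    """Run the fixed preprocessing chain for ``profile``.

    Profiles: ``eeg`` (2-50 Hz bandpass, notch, EOG regression when an EOG
    block is supplied, ICA cleaning, average reference), ``fnirs`` (MBLL for
    intensity input, db4 x 4 wavelet denoising, 0.01-0.7 Hz bandpass, spline
    correction), ``ecg`` (0.5 Hz highpass, notch, R-peak annotation into an
    event table on the report), ``emg`` (20-450 Hz bandpass clipped below
    Nyquist, notch, rectified 4 Hz low-pass envelope appended).

    Returns ``(processed block, PipelineReport)``.
    """
    if profile not in ("eeg", "fnirs", "ecg", "emg"):
        raise ParameterError(f"unknown pipeline profile {profile!r}")
    report = PipelineReport(profile=profile)

    def run(name, fn, blk, **params):
        vb = float(np.var(blk.data))
        try:
            result = fn(blk, **params)
        except Exception as exc:
            raise type(exc)(f"[pipeline step {name!r}] {exc}") from exc
        new_blk = result[0] if isinstance(result, tuple) else result
        report.add(name, {k: v for k, v in params.items()
                          if not isinstance(v, SignalBlock)},
                   new_blk.labels, vb, float(np.var(new_blk.data)))
        return result

    if profile == "eeg":
        block = run("bandpass_2_50", filter_signal, block,
                    spec=FilterSpec("bandpass", 2.0, 50.0))
        block = run(f"notch_{line_freq:g}", filter_signal, block,
                    spec=FilterSpec("notch", line_freq))
        if eog is not None:
            block = run("eog_regression",
                        lambda b, eog: eog_regress(b, eog), block, eog=eog)
        block, rejected = run("ica_clean", ica_clean, block, seed=seed)
        logger.info("ICA rejected components: %s", rejected)
        block = run("average_reference", rereference_average, block)
    elif profile == "fnirs":
        if block.modality == "fnirs_intensity":
            kw = dict(mbll_kwargs or {})
            kw.setdefault("wavelengths",
                          [760.0, 850.0] * (block.n_channels // 2))
            block = run("mbll", mbll, block, **kw)
        block = run("wavelet_db4_l4", wavelet_denoise, block,
                    wavelet="db4", levels=4)
        block = run("bandpass_0.01_0.7", filter_signal, block,
                    spec=FilterSpec("bandpass", 0.01, 0.7))
        block = run("spline_correction", spline_correct, block, z_threshold=3.0)
    elif profile == "ecg":
        block = run("highpass_0.5", filter_signal, block,
                    spec=FilterSpec("highpass", 0.5))
        block = run(f"notch_{line_freq:g}", filter_signal, block,
                    spec=FilterSpec("notch", line_freq))
        vb = float(np.var(block.data))
        peaks = detect_r_peaks(block)
        onsets = block.start_time + peaks / block.rate
        report.events = EventTable(onsets, np.zeros(peaks.size),
                                   ["r_peak"] * peaks.size)
        report.add("r_peak_annotation", {"n_peaks": int(peaks.size)},
                   block.labels, vb, vb)
    else:  # emg
        upper = min(450.0, 0.95 * block.rate / 2.0)
        block = run(f"bandpass_20_{upper:g}", filter_signal, block,
                    spec=FilterSpec("bandpass", 20.0, upper))
        block = run(f"notch_{line_freq:g}", filter_signal, block,
                    spec=FilterSpec("notch", line_freq))
        vb = float(np.var(block.data))
        env_src = block.copy(data=np.abs(block.data))
        env = filter_signal(env_src, FilterSpec("lowpass", high=4.0)).data
        block = block.copy(data=np.vstack([block.data, env]),
                           labels=block.labels + [f"{l}_env"
                                                  for l in block.labels],
                           chromophore=block.chromophore * 2)
        report.add("envelope_4hz", {"rectify": True, "lowpass_hz": 4.0},
                   block.labels, vb, float(np.var(block.data)))
    return block, report
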