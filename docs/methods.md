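# Methods

This note documents the models, conventions and design choices behind the
package, what the simulator does and does not emulate, and the known
limitations. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and alignment

Signals live in a `SignalBlock` (channels × samples, one modality, one
sampling rate) at one of three stages — raw, epoch, evoked — inside a
`Recording` that also carries event tables and metadata. Conventions:
time in seconds, 0-based sample indexing, half-open epoch windows
`[tmin, tmax)`. Epochs touching a recording boundary are dropped, never
zero-padded: padding would fabricate data.

Two alignment strategies exist. *Time-point alignment* assumes a shared
clock: any block whose rate does not divide the fastest rate by an
integer factor is resampled to `r_high / ceil(r_high / r_low)`. This rule
never exceeds the native low rate (no upsampling beyond what was
measured) and guarantees an integer ratio; it is idempotent. *Event-based
alignment* shifts each modality so a shared marker sits at t = 0, crops
to the overlapping span starting at the marker (so the marker lands on
sample 0 in every modality), then applies the same rate harmonization.
Resampling is polyphase (`scipy.signal.resample_poly`) with its built-in
anti-aliasing.

File formats: BDF (24-bit EDF variant) is read and written directly; the
writer uses 1-second records, requires integer rates, and stores the true
sample count in the reserved header field so padding is trimmed on read.
SNIRF (HDF5) support covers continuous-wave intensity (dataType 1) and
processed HbO/HbR series (dataType 99999); other dataTypes are rejected
with an explicit error. The CSV dialect is a samples × channels matrix
with a JSON sidecar (`rate`, `modality`, `labels`, optional chromophore
tags). BIDS-style export produces `sub-<id>/[eeg|nirs|...]/` trees with
data files, JSON sidecars and channels/events TSVs; it is a naming
convention, not a validated BIDS dataset.

## Preprocessing

All frequency-selective filters are Butterworth order 4 applied
forward–backward (zero phase); the notch is an IIR notch with Q = 30.
The line frequency defaults to 60 Hz and is an argument everywhere.
Fixed pipeline orders:

- **eeg** — 2–50 Hz bandpass, notch, EOG regression (when an EOG block is
  supplied), ICA cleaning, average reference.
- **fnirs** — MBLL (for intensity input), db4 wavelet denoising at four
  levels, 0.01–0.7 Hz bandpass, spline artifact correction.
- **ecg** — 0.5 Hz highpass, notch, R-peak annotation into an event
  table.
- **emg** — 20–450 Hz bandpass with the upper edge clipped below Nyquist,
  notch, full-wave rectification + 4 Hz low-pass envelope appended as an
  extra channel.

*EOG regression* subtracts each EEG channel's least-squares projection
onto the EOG channels, leaving residuals orthogonal to the regressors.
*ICA cleaning* (FastICA, seeded) zeroes components whose absolute
correlation with a reference channel exceeds 0.7 or whose Pearson
kurtosis exceeds 3× the median component kurtosis — both thresholds are
arguments. Kurtosis is a blunt instrument: it flags sparse/bursty
artifacts (blinks, electrode pops) but not stationary ones.

*MBLL.* Optical-density change is `−log10(I/Ī)` with `Ī` the channel's
temporal mean; channel pairs at two wavelengths are mapped to ΔHbO/ΔHbR
(µM) through the inverse 2×2 extinction matrix, normalized by
source–detector distance (cm) and a differential pathlength factor
(default 6.0). Default extinction coefficients, in 1/(cm·mM), are
760 nm: (HbO 1.4866, HbR 3.8437) and 850 nm: (HbO 2.5264, HbR 1.7986) —
the values used by common CW-NIRS processing tools; both the table and
the DPF are overridable. Because `Ī` fixes the baseline, concentrations
are recovered exactly up to a per-channel constant; dynamics are exact.

*Wavelet denoising* is a self-contained periodized orthonormal db4 filter
bank (the synthesis operator is the transpose of the analysis operator,
giving machine-precision reconstruction) with soft thresholding at the
universal threshold `σ̂ √(2 ln n)`, `σ̂` from the median absolute
deviation of the finest detail level. The MAD estimate needs a noise
floor: on a noise-free signal the threshold collapses to ~0 and the
operation is a near-identity, which is the correct behavior.

*Spline correction* flags regions where the 1 s moving standard deviation
exceeds `z × median` (default z = 3), merges flagged runs closer than 5 s
(a plateau artifact only spikes the moving std at its two edges), fits a
least-squares cubic spline baseline (interior knots every 1 s) inside
each segment and subtracts its interior component — baseline minus the
chord between its endpoint values — which enforces continuity at the
segment edges. Detection and correction iterate to a fixpoint, making
the operation idempotent.

*R-peak detection* follows the classic energy pipeline: 5–15 Hz bandpass,
derivative, squaring, 150 ms moving-window integration, a threshold
proportional to the integrated signal's 99th percentile (hence
scale-invariant), a 200 ms refractory period, and refinement to the local
extremum of the bandpassed ECG.

## Features

Welch PSD uses Hann windows, 2 s segments, 50 % overlap by default.
Canonical bands: delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma
30 Hz up to min(100 Hz, 0.9 × Nyquist). Relative band power divides by
total 0.5 Hz–Nyquist power, so the fractions sum to 1 only when the
scheme covers that whole range (the capped gamma band does not; tests
that assert the sum extend gamma to Nyquist). HRV: SDNN uses the n−1
denominator, pNN50 the fixed 50 ms threshold; LF (0.04–0.15 Hz) and HF
(0.15–0.4 Hz) powers come from a Lomb–Scargle periodogram of the RR
tachogram — no resampling, hence no interpolation bias — and are only
computed when ≥ 2 minutes of data are present. Sample entropy uses
Chebyshev distance with both template counts over N − m templates and a
tolerance floor of 1e-12 so constant series stay defined (SampEn = 0).
The aperiodic fit is an ordinary least-squares line in log10–log10
coordinates; narrow oscillatory peaks bias the exponent upward, which the
tests bound rather than model. EMG synergies use scikit-learn NMF
(multiplicative updates, deterministic NNDSVD-A initialization).
Connectivity is band-averaged magnitude-squared coherence per channel
pair: symmetric, unit diagonal, entries in [0, 1].

## Coupling

NVC is `|Pearson r|` between the HRF-convolved band-power time course and
a hemoglobin series. The band-power series is demeaned before
convolution (the usual GLM-regressor convention); this makes the
correlation exactly invariant to affine rescaling of either input and
avoids a kernel ramp-in artifact from the DC level. The default band is
alpha+beta (8–30 Hz) with a 2 s power window stepped at the fNIRS sample
period; all of it is configurable. Dynamic NVC applies the static
estimator per sliding window (window ≥ 3× the HRF peak time so a full
response fits) and summarizes by the mean |r|.

CMC uses non-overlapping segments precisely so the independence
assumption behind the analytic threshold `1 − p^(1/(L−1))` holds exactly;
the DC and Nyquist bins are excluded from calibration checks because
per-segment detrending biases them. HBI interpolates instantaneous heart
rate (60/RR at interval midpoints) to the band-power rate and correlates
per window; zero-variance windows become NaN — explicitly missing rather
than silently zero. Condition comparisons are two-tailed paired t-tests
per channel with Holm (family-wise) or Benjamini–Hochberg (FDR)
correction via statsmodels.

## Modeling

CSP: per-epoch covariances are trace-normalized (removing per-trial gain
differences) and averaged per class; the composite covariance is
whitened; the whitened class-1 covariance is eigendecomposed; the top and
bottom `n_components/2` eigenvectors (default 2 + 2), mapped back through
the whitener, are the spatial filters. Patterns are columns of the
inverse of the *full* filter matrix — the forward topographies — not the
pseudoinverse of the reduced one, which would give minimum-norm vectors
instead. A ridge of 1e-6 × trace handles singular composites.
Eigenvalues are the class-1 variance ratios, so swapping class labels
reverses and complements them.

Cross-validation is stratified k-fold (default 10), seeded. When epochs
rather than precomputed features enter a CV loop, the CSP filters are
refitted inside every training fold: fitting them once on all data leaks
test covariance into the filters and inflates accuracy above chance on
null data. Classifier selection is a small deterministic grid over
{linear SVM, RBF SVM, random forest} scored by CV accuracy. Stacking
trains a linear-SVM meta-classifier on base-model class probabilities
produced on held-out folds only (5-fold out-of-fold within each outer
training fold); probabilities, not decision values, are stacked. SVM
probabilities come from cross-validated calibration
(`CalibratedClassifierCV`, single calibrated model).

The external-model registry validates descriptor JSONs (name,
description, weights path, definition path, inference entry, input/output
specs, with referenced files present) and reports *all* missing items in
one error; it never executes the described model.

## Workflow engine

Nodes belong to eight categories (data input, preprocessing, feature
extraction, coupling, machine learning, statistical analysis, plotting,
general) and expose typed ports. Validation is two-stage: Kahn's
algorithm for acyclicity (structural errors such as dangling edges are
reported first; on failure one concrete cycle is returned, extracted
after peeling non-cycle descendants), then the node-connection-rule
table — shipped as an editable JSON asset (`assets/ncr.json`) mapping
each source port type to its permitted target types, plus the entry rule
that every in-degree-0 node must be a data-input node. The default table
is identity-typed (like connects to like, plus a wildcard `any`), which
encodes the two hard rules — workflows begin with data input, EEG
preprocessing accepts only EEG data — while letting users extend the
vocabulary.

Execution runs in deterministic (lexicographically tie-broken)
topological order; each node's outputs fan out to all consumers
unchanged; plotting nodes are strict pass-throughs. A failing node is
logged with its error and all its descendants are marked skipped rather
than aborting the whole run, so partial results survive. Debug runs bind
every data-input node to simulator output matching its declared port
type (10 s, 4 channels, modality-typical rates) — a graph that completes
all-ok is preliminarily verified. App generation validates the graph
(including a trained-model reference on every machine-learning node),
saves it next to a generated runner script plus a manifest with a
workflow hash; it deliberately stops at a runnable script — binary
packaging is environment-specific.

## Simulator: the stated world

Every generator is a pure function of (parameters, seed) — bit-identical
regeneration — and returns a `GroundTruth` record of what was injected.

- `sim_eeg`: band-limited oscillations (FFT brick-wall noise at specified
  RMS amplitudes) over 1/f^χ background noise.
- `sim_coupled_fnirs`: HbO is the standardized HRF-convolved EEG band
  power plus Gaussian noise with variance `1/ρ² − 1`, so the population
  correlation equals the requested coupling ρ analytically — no
  rejection sampling; HbR is −0.3 × HbO plus independent noise.
- `sim_emg_with_drive`: a 2 Hz-wide shared drive at the requested
  frequency; the SNR is defined *in band* (drive power over each signal's
  own background power within the drive band), so the expected peak
  coherence is `(snr/(1+snr))²` and the small-SNR limit genuinely
  vanishes.
- `sim_ecg`: RR series = mean + 0.1 Hz LF sinusoid + 0.25 Hz HF sinusoid
  + jitter; Mexican-hat QRS pulses at cumulative RR times. Adequate for
  peak-detection and HRV tests, not for morphology studies.
- `sim_mi_dataset`: two-class epochs; EEG sources are 8–30 Hz band
  noise with the first two source variances scaled by (1 + effect) and
  its inverse in opposite directions per class, mixed through a random
  orthonormal matrix (CSP-recoverable by construction); hemoglobin
  epochs carry an HRF-shaped bump whose amplitude is lateralized by
  class in proportion to the effect size, plus noise at SD 0.3. Effect
  size 0 makes the classes exchangeable.

What a green test establishes: that the estimators recover what this
generative model injects, at the stated sizes and noise levels. What it
does not establish: robustness to real-recording phenomena the simulator
omits — nonstationarity, electrode drift and pops, motion artifacts,
physiological confounds (Mayer waves, respiration in fNIRS), volume
conduction beyond linear mixing, or inter-subject variability.

## Numerical choices and degenerate inputs

Zero-variance inputs to correlation-based couplings raise explicit
errors (static) or yield NaN windows (sliding). Degenerate epochs (zero
variance after spatial filtering) are an error, not a silent −inf.
Constant channels carry NaN Hjorth mobility as an explicit missing
marker. BDF quantization is 24-bit against the header-rounded physical
range; round-trips are exact within two quantization steps. The wavelet
transform pads to a multiple of 2^levels by edge replication and trims
after reconstruction.

## Limitations

- BDF writing requires integer sampling rates; EDF+ annotations are not
  supported.
- SNIRF support is deliberately minimal (CW intensity and processed Hb);
  channel labels round-trip through a custom `channelLabels` dataset.
- The HBI definition (band power vs. instantaneous HR correlation) is
  one reasonable operationalization of heart–brain interaction among
  several in use.
- No GPU, no deep-learning model zoo, no AutoML: classifier selection is
  a small explicit grid.
- The NCR default table is intentionally permissive beyond its two hard
  rules; stricter site-specific tables can be dropped in as JSON.
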