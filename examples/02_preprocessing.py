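"""Automatic preprocessing pipelines for EEG, fNIRS intensity and ECG.

Each profile runs a fixed ordered chain of cleaning steps and reports what
it did; the fNIRS chain converts raw intensities to HbO/HbR via the
modified Beer-Lambert law.
"""

import numpy as np

from neurofuse.containers import SignalBlock
from neurofuse.preprocess import mbll_forward, run_auto_pipeline
from neurofuse.simulate import sim_ecg, sim_eeg

# --- EEG: bandpass, notch, EOG regression, ICA, average reference --------
eeg = sim_eeg(channels=6, duration_s=20.0, rate=250.0, seed=0)
eog = SignalBlock("eog", 20.0 * np.random.default_rng(1)
                  .standard_normal((1, eeg.n_samples)), 250.0, ["EOG"])
clean, report = run_auto_pipeline(eeg, "eeg", eog=eog, seed=0)
print("EEG pipeline steps:", " -> ".join(report.step_names))
print(f"  channel-mean after average reference: "
      f"{np.abs(clean.data.sum(axis=0)).max():.2e} (should be ~0)")

# --- fNIRS: MBLL, wavelet denoise, bandpass, spline correction -----------
n = 1200
hbo = 0.5 * np.sin(2 * np.pi * 0.05 * np.arange(n) / 10.0)
inten = mbll_forward(hbo, -0.3 * hbo, [1.0, 1.0], [760.0, 850.0])
raw = SignalBlock("fnirs_intensity", inten, 10.0, ["S1-D1_760", "S1-D1_850"])
hb, report = run_auto_pipeline(raw, "fnirs")
print("fNIRS pipeline steps:", " -> ".join(report.step_names))
print(f"  output modality {hb.modality}, chromophores {hb.chromophore}")

# --- ECG: filtering plus R-peak annotation --------------------------------
ecg, gt = sim_ecg(duration_s=30.0, rate=250.0, seed=2)
_, report = run_auto_pipeline(ecg, "ecg")
print(f"ECG pipeline found {len(report.events)} R peaks "
      f"(simulator placed {len(gt.r_peak_times_s)})")
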