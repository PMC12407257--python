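"""Two-class decoding: CSP features, classifier selection, stacking.

The simulator builds motor-imagery-style EEG and hemoglobin epochs whose
class difference is controlled by an effect size; CSP log-variance
features feed per-modality classifiers whose probabilities a linear-SVM
meta-classifier fuses.
"""

from neurofuse.modeling import csp_crossval, csp_fit, stacked_cv_accuracy
from neurofuse.simulate import sim_mi_dataset

eeg, fnirs, gt = sim_mi_dataset(trials_per_class=40, effect_size=2.0, seed=7)
print(f"{eeg.n_epochs} trials, {eeg.n_channels} EEG channels, "
      f"{fnirs.n_channels} HbO channels")

model = csp_fit(eeg, n_components=4)
print("CSP eigenvalues (class-variance ratios):",
      [round(float(v), 3) for v in model.eigenvalues])
print("  (values far from 0.5 mean strong class contrast)")

base_kinds = {}
for name, es in (("eeg", eeg), ("hbo", fnirs)):
    acc, _ = csp_crossval(es, "linear_svm", k=10, seed=1)
    base_kinds[name] = "linear_svm"
    print(f"10-fold CV accuracy, {name} CSP + linear SVM: {acc:.3f}")

stacked, folds = stacked_cv_accuracy({"eeg": eeg, "hbo": fnirs}, eeg.labels,
                                     base_kinds, k=10, seed=1)
print(f"stacked ensemble accuracy: {stacked:.3f} "
      f"(meta-classifier fuses per-modality probabilities)")
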