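"""CSP spatial filtering, classifier evaluation, stacking, model registry.

The common-spatial-patterns solver is implemented here (trace-normalized
epoch covariances, whitening of the composite covariance, eigendecomposition
of the whitened class-1 covariance); classifier fitting, stratified
cross-validation and the stacking meta-classifier stand on scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import (StratifiedKFold, cross_val_predict,
                                     cross_val_score)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import EpochSet
from .errors import InputError, NumericalError, ParameterError, SchemaError, \
    DescriptorError
from .features import FeatureSet


@dataclass
class CSPModel:
    """Fitted common-spatial-patterns model.

    ``filters`` (components x channels) project epochs onto discriminative
    sources; ``patterns`` (channels x components) are the corresponding
    forward topographies; ``eigenvalues`` are the class-1 variance ratios in
    [0, 1], sorted by discriminability (most class-1-dominant first, then
    most class-2-dominant).
    """

    filters: np.ndarray
    patterns: np.ndarray
    eigenvalues: np.ndarray
    n_components: int
    classes: tuple[str, str] = ("0", "1")


def _epoch_covariances(data: np.ndarray) -> np.ndarray:
    """Trace-normalized covariance per epoch, averaged."""
    covs = []
    for ep in data:
        c = ep @ ep.T / ep.shape[1]
        tr = np.trace(c)
        if tr <= 0:
            raise InputError("epoch with zero total variance")
        covs.append(c / tr)
    return np.mean(covs, axis=0)


def csp_fit(epochs: EpochSet, n_components: int = 4) -> CSPModel:
    """Fit CSP filters on a two-class epoch set.

    The composite covariance is whitened; eigenvectors of the whitened
    class-1 covariance with the largest and smallest eigenvalues give the
    ``n_components/2 + n_components/2`` spatial filters.  A ridge of
    1e-6 x trace is added if the composite covariance is singular.
    """
    classes = sorted(set(epochs.labels))
    if len(classes) != 2:
        raise InputError(f"CSP needs exactly 2 classes, got {len(classes)}")
    if n_components % 2 or n_components < 2:
        raise ParameterError("n_components must be a positive even integer")
    if n_components > epochs.n_channels:
        raise ParameterError("n_components cannot exceed channel count")
    labels = np.asarray(epochs.labels)
    groups = [epochs.data[labels == c] for c in classes]
    if any(len(g) < 2 for g in groups):
        raise InputError("each class needs at least 2 epochs")
    c1 = _epoch_covariances(groups[0])
    c2 = _epoch_covariances(groups[1])
    comp = c1 + c2
    eva, eve = np.linalg.eigh(comp)
    if eva[0] < 1e-10 * eva[-1]:
        ridge = 1e-6 * np.trace(comp)
        comp = comp + ridge * np.eye(comp.shape[0])
        eva, eve = np.linalg.eigh(comp)
    whitener = eve @ np.diag(1.0 / np.sqrt(eva)) @ eve.T
    s1 = whitener @ c1 @ whitener.T
    lam, vec = np.linalg.eigh((s1 + s1.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    half = n_components // 2
    keep = np.concatenate([np.arange(half),
                           np.arange(len(lam) - half, len(lam))])
    filters_full = vec.T @ whitener          # all components
    patterns_full = np.linalg.inv(filters_full)  # forward topographies
    filters = filters_full[keep]
    patterns = patterns_full[:, keep]
    return CSPModel(filters=filters, patterns=patterns,
                    eigenvalues=np.clip(lam[keep], 0.0, 1.0),
                    n_components=n_components,
                    classes=(str(classes[0]), str(classes[1])))


def csp_transform(model: CSPModel, epochs: EpochSet) -> FeatureSet:
    """Log-variance CSP features, normalized by total retained variance."""
    if epochs.n_channels != model.filters.shape[1]:
        raise InputError(
            f"epochs have {epochs.n_channels} channels, model expects "
            f"{model.filters.shape[1]}")
    rows = []
    for ep in epochs.data:
        proj = model.filters @ ep
        var = proj.var(axis=1)
        total = var.sum()
        if total <= 0 or np.any(var <= 0):
            raise NumericalError("degenerate epoch: zero variance after "
                                 "spatial filtering")
        rows.append(np.log(var / total))
    names = [f"csp{i}" for i in range(model.n_components)]
    return FeatureSet(np.array(rows), names, units=["log"] * len(names),
                      provenance={"op": "csp_transform",
                                  "eigenvalues": model.eigenvalues.tolist()})


# ---------------------------------------------------------------------------
# Classifiers


def make_classifier(kind: str, seed: int = 0):
    """Factory for the supported base classifiers (all expose predict_proba)."""
    from sklearn.calibration import CalibratedClassifierCV

    if kind == "linear_svm":
        return make_pipeline(StandardScaler(), CalibratedClassifierCV(
            SVC(kernel="linear", random_state=int(seed)), ensemble=False))
    if kind == "rbf_svm":
        return make_pipeline(StandardScaler(), CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=int(seed)), ensemble=False))
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=int(seed))
    raise ParameterError(f"unknown model kind {kind!r}")


def crossval_score(features: FeatureSet | np.ndarray, labels, kind: str,
                   k: int = 10, seed: int = 0):
    """Stratified k-fold cross-validation accuracy.

    Returns ``(mean accuracy, per-fold accuracies)``; deterministic for a
    fixed seed.
    """
    X = features.values if isinstance(features, FeatureSet) else \
        np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("need at least 2 classes")
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > counts.min():
        raise ParameterError(
            f"k={k} exceeds the smallest class count ({counts.min()})")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    scores = cross_val_score(make_classifier(kind, seed), X, y, cv=cv)
    return float(scores.mean()), scores


def grid_select(features, labels, kinds=("linear_svm", "rbf_svm",
                                         "random_forest"),
                k: int = 10, seed: int = 0):
    """Pick the best classifier kind by k-fold CV accuracy.

    A small deterministic stand-in for automated model search: every listed
    kind is scored with :func:`crossval_score` and the winner returned as
    ``(kind, mean accuracy)``.
    """
    best = None
    for kind in kinds:
        mean, _ = crossval_score(features, labels, kind, k=k, seed=seed)
        if best is None or mean > best[1]:
            best = (kind, mean)
    return best


# ---------------------------------------------------------------------------
# Stacking


def out_of_fold_probabilities(features, labels, kind: str, k: int = 5,
                              seed: int = 0) -> np.ndarray:
    """Class-probability matrix predicted only on held-out folds."""
    X = features.values if isinstance(features, FeatureSet) else \
        np.asarray(features, dtype=float)
    y = np.asarray(labels)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    return cross_val_predict(make_classifier(kind, seed), X, y, cv=cv,
                             method="predict_proba")


@dataclass
class StackedEnsemble:
    """Linear-SVM meta-classifier over base-model class probabilities."""

    meta: object
    base_names: list[str] = field(default_factory=list)

    def predict(self, base_probabilities: list[np.ndarray]) -> np.ndarray:
        return self.meta.predict(np.hstack(base_probabilities))


def stack_ensemble(base_probabilities: list[np.ndarray], labels,
                   seed: int = 0, base_names=None) -> StackedEnsemble:
    """Train the stacking meta-classifier on out-of-fold probabilities.

    ``base_probabilities`` is one (n_samples x n_classes) matrix per base
    model, produced on held-out folds only (no leakage).
    """
    if len(base_probabilities) < 2:
        raise InputError("stacking needs at least 2 base models")
    n = len(np.asarray(labels))
    for i, P in enumerate(base_probabilities):
        if np.asarray(P).shape[0] != n:
            raise InputError(
                f"base model {i} produced {np.asarray(P).shape[0]} rows for "
                f"{n} labels")
    Z = np.hstack([np.asarray(P, dtype=float) for P in base_probabilities])
    meta = make_pipeline(StandardScaler(),
                         SVC(kernel="linear", random_state=int(seed)))
    meta.fit(Z, np.asarray(labels))
    return StackedEnsemble(meta=meta,
                           base_names=list(base_names or
                                           map(str,
                                               range(len(base_probabilities)))))


def csp_crossval(epochs: EpochSet, kind: str = "linear_svm",
                 n_components: int = 4, k: int = 10, seed: int = 0):
    """k-fold CV accuracy with CSP refitted inside every training fold.

    Fitting the spatial filters on the full data before cross-validating
    leaks test-epoch covariance into the filters and inflates accuracy, so
    the filters are estimated per fold.  Returns
    ``(mean accuracy, per-fold accuracies)``.
    """
    y = np.asarray(epochs.labels)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    accs = []
    for train, test in cv.split(np.zeros(len(y)), y):
        Xtr, Xte = _csp_fold_features(epochs, train, test, n_components)
        clf = make_classifier(kind, seed).fit(Xtr, y[train])
        accs.append(float(np.mean(clf.predict(Xte) == y[test])))
    return float(np.mean(accs)), np.asarray(accs)


def _csp_fold_features(epochs: EpochSet, train, test, n_components: int = 4):
    """CSP features for one CV fold, filters fitted on the training part."""
    sub = EpochSet(epochs.data[train], [epochs.labels[i] for i in train],
                   epochs.tmin, epochs.tmax, epochs.rate,
                   epochs.source_modality, ch_names=epochs.ch_names)
    model = csp_fit(sub, n_components)
    te = EpochSet(epochs.data[test], [epochs.labels[i] for i in test],
                  epochs.tmin, epochs.tmax, epochs.rate,
                  epochs.source_modality, ch_names=epochs.ch_names)
    return csp_transform(model, sub).values, csp_transform(model, te).values


def stacked_cv_accuracy(modalities: dict, labels, base_kinds: dict,
                        k: int = 10, inner_k: int = 5, seed: int = 0,
                        n_components: int = 4):
    """Cross-validated accuracy of the full stacking pipeline.

    ``modalities`` maps a name to either an :class:`EpochSet` (CSP features
    are extracted with filters fitted inside each outer training fold) or a
    precomputed :class:`FeatureSet`/array.  For each outer fold the base
    models produce inner out-of-fold probabilities on the training part,
    the linear-SVM meta-classifier is fitted on them, and accuracy is
    measured on the untouched test part.  Returns
    ``(mean accuracy, per-fold accuracies)``.
    """
    y = np.asarray(labels)
    names = list(modalities)
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    accs = []
    for train, test in outer.split(np.zeros(len(y)), y):
        oof, test_probs = [], []
        for m in names:
            src = modalities[m]
            if isinstance(src, EpochSet):
                Xtr, Xte = _csp_fold_features(src, train, test, n_components)
            else:
                X = src.values if isinstance(src, FeatureSet) else \
                    np.asarray(src, dtype=float)
                Xtr, Xte = X[train], X[test]
            kind = base_kinds[m]
            inner = StratifiedKFold(n_splits=inner_k, shuffle=True,
                                    random_state=int(seed))
            clf = make_classifier(kind, seed)
            oof.append(cross_val_predict(clf, Xtr, y[train], cv=inner,
                                         method="predict_proba"))
            fitted = make_classifier(kind, seed).fit(Xtr, y[train])
            test_probs.append(fitted.predict_proba(Xte))
        meta = make_pipeline(StandardScaler(),
                             SVC(kernel="linear", random_state=int(seed)))
        meta.fit(np.hstack(oof), y[train])
        pred = meta.predict(np.hstack(test_probs))
        accs.append(float(np.mean(pred == y[test])))
    return float(np.mean(accs)), np.asarray(accs)


# ---------------------------------------------------------------------------
# External model registry


@dataclass
class ModelDescriptor:
    """Registry entry for an externally trained model."""

    name: str
    description: str
    weights_path: Path
    definition_path: Path
    inference_entry: str
    input_spec: dict
    output_spec: dict


REQUIRED_DESCRIPTOR_FIELDS = ("name", "description", "weights_path",
                              "definition_path", "inference_entry",
                              "input_spec", "output_spec")


def register_external_model(descriptor_path) -> ModelDescriptor:
    """Validate an external-model descriptor JSON and return the entry.

    Checks that every required field is present and that the referenced
    weight/definition files exist; the model itself is never executed.
    A single :class:`DescriptorError` lists *all* missing items.
    """
    descriptor_path = Path(descriptor_path)
    try:
        payload = json.loads(descriptor_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"cannot parse descriptor {descriptor_path}: {exc}") \
            from exc
    missing = [f for f in REQUIRED_DESCRIPTOR_FIELDS
               if f not in payload or payload[f] in (None, "", {}, [])]
    root = descriptor_path.parent
    for key in ("weights_path", "definition_path"):
        if key in payload and payload.get(key):
            p = root / payload[key]
            if not p.exists():
                missing.append(f"{key} (file {p} not found)")
    if missing:
        raise DescriptorError(missing)
    return ModelDescriptor(
        name=payload["name"], description=payload["description"],
        weights_path=root / payload["weights_path"],
        definition_path=root / payload["definition_path"],
        inference_entry=payload["inference_entry"],
        input_spec=payload["input_spec"], output_spec=payload["output_spec"])
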