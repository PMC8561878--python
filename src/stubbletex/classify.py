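"""Patch classifiers and their tenfold cross-validated evaluation.

Three classical classifier families operate on texture feature tables:
random forest (RF), a single-hidden-layer back-propagation network
(BPNN) and support vector machines (SVM) with four kernels.  Evaluation
accumulates a 3-class confusion matrix over the held-out folds of a
stratified tenfold cross-validation and reports

* accuracy  Ac = (TP + TN) / (TP + TN + FP + FN)  over all classes,
* sensitivity Se = TP / (TP + FN),
* specificity Sp = TN / (TN + FP),

where stubble is the positive class and the two other classes (soil
and broken leaves between rows; residual film) are pooled as negative.
High sensitivity means stubble is rarely missed; high specificity means
background texture is rarely mistaken for stubble.

Features are z-score standardized with statistics of the training fold
only, so no information leaks from held-out folds.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CLASS_ORDER",
    "POSITIVE_CLASS",
    "ModelSpec",
    "TrainedModel",
    "EvalReport",
    "metrics_from_confusion",
    "train",
    "predict",
    "evaluate_cv",
]

#: Fixed confusion-matrix class order: A = soil and broken leaves,
#: B = stubble, C = residual film.
CLASS_ORDER = ("soil_leaves", "stubble", "film")

#: The positive class for sensitivity/specificity.
POSITIVE_CLASS = "stubble"

_SVM_KERNELS = {"linear", "polynomial", "radial_basis", "sigmoid"}
_SKLEARN_KERNEL = {
    "linear": "linear",
    "polynomial": "poly",
    "radial_basis": "rbf",
    "sigmoid": "sigmoid",
}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus its hyper-parameters.

    family
        One of ``RF``, ``BPNN``, ``SVM``.
    kernel
        SVM kernel (``linear``, ``polynomial``, ``radial_basis``,
        ``sigmoid``); required for SVM, forbidden otherwise.
    hyperparams
        Overrides passed to the underlying estimator (e.g.
        ``{"n_estimators": 200}`` for RF, ``{"max_iter": 300}`` for
        BPNN, ``{"C": 10.0}`` for SVM).
    """

    family: str = "BPNN"
    kernel: str | None = None
    hyperparams: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in {"RF", "BPNN", "SVM"}:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "SVM":
            if self.kernel not in _SVM_KERNELS:
                raise ValueError(
                    f"SVM needs a kernel from {sorted(_SVM_KERNELS)}, got {self.kernel!r}"
                )
        elif self.kernel is not None:
            raise ValueError(f"kernel is only meaningful for SVM, not {self.family}")

    def build(self) -> Pipeline:
        """A fresh scaler+estimator pipeline for this spec."""
        hp = dict(self.hyperparams)
        if self.family == "RF":
            est = RandomForestClassifier(
                n_estimators=hp.pop("n_estimators", 100),
                random_state=self.seed,
                **hp,
            )
        elif self.family == "BPNN":
            est = MLPClassifier(
                hidden_layer_sizes=hp.pop("hidden_layer_sizes", (32,)),
                activation=hp.pop("activation", "logistic"),
                max_iter=hp.pop("max_iter", 500),
                random_state=self.seed,
                **hp,
            )
        else:
            est = SVC(
                kernel=_SKLEARN_KERNEL[self.kernel],
                C=hp.pop("C", 1.0),
                degree=hp.pop("degree", 3),
                gamma=hp.pop("gamma", "scale"),
                random_state=self.seed,
                **hp,
            )
        return Pipeline([("scale", StandardScaler()), ("clf", est)])

    @property
    def label(self) -> str:
        return self.family if self.kernel is None else f"SVM-{self.kernel}"


@dataclass
class TrainedModel:
    """A fitted pipeline together with the feature layout it expects."""

    spec: ModelSpec
    pipeline: Pipeline
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]


@dataclass
class EvalReport:
    """Confusion matrix and Ac/Se/Sp from cross-validated predictions.

    The confusion matrix has true classes on rows and predicted classes
    on columns, in the fixed order soil_leaves (A), stubble (B),
    film (C).
    """

    confusion: np.ndarray
    Ac: float
    Se: float
    Sp: float
    per_fold: list[dict]
    timing_per_sample: float
    spec: ModelSpec | None = None

    def to_json(self, path) -> None:
        payload = {
            "class_order": list(CLASS_ORDER),
            "confusion": self.confusion.tolist(),
            "Ac": self.Ac,
            "Se": self.Se,
            "Sp": self.Sp,
            "per_fold": self.per_fold,
            "timing_per_sample_s": self.timing_per_sample,
            "model": None if self.spec is None else {
                "family": self.spec.family,
                "kernel": self.spec.kernel,
                "hyperparams": dict(self.spec.hyperparams),
                "seed": self.spec.seed,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _validate_features(features: np.ndarray) -> np.ndarray:
    feats = np.asarray(features, dtype=np.float64)
    if feats.ndim != 2:
        raise ValueError("feature table must be 2-D (samples x features)")
    if not np.all(np.isfinite(feats)):
        raise ValueError("feature table contains NaN or Inf")
    return feats


def metrics_from_confusion(confusion: np.ndarray,
                           positive: str = POSITIVE_CLASS) -> tuple[float, float, float]:
    """(Ac, Se, Sp) of a confusion matrix in the fixed class order.

    Accuracy is the trace ratio over all classes; sensitivity and
    specificity pool the non-positive classes as negative.
    """
    cm = np.asarray(confusion, dtype=np.float64)
    if cm.shape[0] != cm.shape[1] or cm.shape[0] != len(CLASS_ORDER):
        raise ValueError(f"expected a {len(CLASS_ORDER)}x{len(CLASS_ORDER)} matrix")
    pos = CLASS_ORDER.index(positive)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    ac = np.trace(cm) / total
    tp = cm[pos, pos]
    fn = cm[pos, :].sum() - tp
    fp = cm[:, pos].sum() - tp
    tn = total - tp - fn - fp
    se = tp / (tp + fn) if tp + fn > 0 else 0.0
    sp = tn / (tn + fp) if tn + fp > 0 else 0.0
    return float(ac), float(se), float(sp)


def train(features, labels: Sequence[str], spec: ModelSpec,
          feature_names: Sequence[str] | None = None) -> TrainedModel:
    """Fit one classifier on a full feature table.

    Deterministic under a fixed ``spec.seed``.  The trained model
    remembers the feature layout and refuses mismatched tables at
    prediction time.
    """
    feats = _validate_features(features)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training needs at least 2 classes")
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(feats.shape[1]))
    feature_names = tuple(feature_names)
    if len(feature_names) != feats.shape[1]:
        raise ValueError("feature_names length does not match feature table width")
    pipeline = spec.build()
    pipeline.fit(feats, labels)
    return TrainedModel(
        spec=spec,
        pipeline=pipeline,
        feature_names=feature_names,
        classes=tuple(pipeline.classes_),
    )


def predict(model: TrainedModel, features,
            feature_names: Sequence[str] | None = None) -> np.ndarray:
    """Predict one label per feature row; deterministic."""
    feats = _validate_features(np.atleast_2d(features))
    if feats.shape[1] != len(model.feature_names):
        raise ValueError(
            f"feature table has {feats.shape[1]} columns; the model was "
            f"trained on {len(model.feature_names)}"
        )
    if feature_names is not None:
        mismatched = [
            f"{got!r} (expected {want!r})"
            for got, want in zip(feature_names, model.feature_names)
            if got != want
        ]
        if mismatched:
            raise ValueError("feature layout mismatch: " + "; ".join(mismatched[:5]))
    return model.pipeline.predict(feats)


def evaluate_cv(features, labels: Sequence[str], spec: ModelSpec,
                folds: int = 10, seed: int = 0) -> EvalReport:
    """Stratified k-fold cross-validated confusion matrix and metrics.

    The confusion matrix is accumulated over the held-out folds, so
    every sample is predicted exactly once by a model that never saw
    it.  Fold assignment is a deterministic function of the labels,
    fold count and seed.
    """
    feats = _validate_features(features)
    labels = np.asarray(labels)
    present = [c for c in CLASS_ORDER if c in labels]
    extra = set(np.unique(labels)) - set(CLASS_ORDER)
    if extra:
        raise ValueError(f"unknown labels {sorted(extra)}; expected {CLASS_ORDER}")
    counts = {c: int(np.sum(labels == c)) for c in present}
    smallest = min(counts.values())
    if folds > smallest:
        raise ValueError(
            f"{folds}-fold CV impossible: smallest class has {smallest} samples"
        )

    index = {c: i for i, c in enumerate(CLASS_ORDER)}
    confusion = np.zeros((len(CLASS_ORDER), len(CLASS_ORDER)), dtype=np.int64)
    per_fold = []
    elapsed = 0.0
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    base = spec.build()
    for fold, (tr, te) in enumerate(splitter.split(feats, labels)):
        pipeline = clone(base)
        pipeline.fit(feats[tr], labels[tr])
        tic = time.perf_counter()
        pred = pipeline.predict(feats[te])
        elapsed += time.perf_counter() - tic
        fold_cm = np.zeros_like(confusion)
        for t, p in zip(labels[te], pred):
            fold_cm[index[t], index[p]] += 1
        confusion += fold_cm
        ac, se, sp = metrics_from_confusion(fold_cm)
        per_fold.append({"fold": fold, "Ac": ac, "Se": se, "Sp": sp,
                         "n_test": int(len(te))})

    ac, se, sp = metrics_from_confusion(confusion)
    return EvalReport(
        confusion=confusion,
        Ac=ac, Se=se, Sp=sp,
        per_fold=per_fold,
        timing_per_sample=elapsed / len(labels),
        spec=spec,
    )
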