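"""Classifier families with a uniform train/predict/score contract.

Four kinds:

* ``ann`` — fully connected feed-forward network (ANN-nl-nu: nl hidden
  layers of nu units each), tanh activations, cross-entropy objective,
  Adam optimizer, early stopping on an internal 15% validation split of the
  (possibly augmented) training pool. Softmax class-probability outputs;
  prediction is the argmax, ties resolved toward the lowest class index.
* ``msvm`` — multiclass SVM: one-vs-one linear-kernel ensemble with
  majority voting. Deterministic: refits on fixed data give identical
  models regardless of seed.
* ``rf`` — random forest, Gini criterion, bootstrap sampling (default 100
  trees); seed-dependent like the ANN.
* ``pca_msvm`` — PCA projection onto nv components fitted on the training
  data (training mean centring, no whitening), then the same linear MSVM in
  the reduced space (PCA-nv-MSVM).

No feature scaling is applied by default; ``standardize=True`` inserts a
train-fitted standardizer for all kinds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import Dataset

__all__ = ["ClassifierSpec", "FittedModel", "EvalReport", "train", "evaluate",
           "pca_project"]

KINDS = ("ann", "msvm", "rf", "pca_msvm")


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind plus the hyperparameters that name it.

    Naming convention: ANN-nl-nu (nl hidden layers, nu units each) and
    PCA-nv-MSVM (nv retained components).
    """

    kind: str = "ann"
    nl: int = 3
    nu: int = 50
    n_trees: int = 100
    nv: int = 3
    seed: int = 0
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; one of {KINDS}")
        if self.kind == "ann" and (self.nl < 1 or self.nu < 1):
            raise ValueError("ann requires nl >= 1 and nu >= 1")
        if self.kind == "rf" and self.n_trees < 1:
            raise ValueError("rf requires n_trees >= 1")
        if self.kind == "pca_msvm" and self.nv < 1:
            raise ValueError("pca_msvm requires nv >= 1")

    @property
    def name(self) -> str:
        if self.kind == "ann":
            return f"ANN-{self.nl}-{self.nu}"
        if self.kind == "pca_msvm":
            return f"PCA-{self.nv}-MSVM"
        return self.kind.upper()

    def with_seed(self, seed: int) -> "ClassifierSpec":
        return ClassifierSpec(
            self.kind, self.nl, self.nu, self.n_trees, self.nv, seed,
            self.standardize,
        )


@dataclass
class FittedModel:
    """Trained classifier with its preprocessing state and class inventory."""

    spec: ClassifierSpec
    estimator: object
    classes: tuple[int, ...]
    n_features: int
    scaler: StandardScaler | None = None
    pca: PCA | None = None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.scaler is not None:
            X = self.scaler.transform(X)
        if self.pca is not None:
            X = self.pca.transform(X)
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature-length mismatch: got {X.shape[1]}, trained on "
                f"{self.n_features}"
            )
        Xt = self._transform(X)
        if self.spec.kind == "ann":
            # Argmax over class probabilities; np.argmax takes the lowest
            # index on ties, and estimator classes are sorted ascending.
            proba = self.estimator.predict_proba(Xt)
            return np.asarray(self.estimator.classes_)[np.argmax(proba, axis=1)]
        return np.asarray(self.estimator.predict(Xt))

    def predict_proba(self, X: np.ndarray) -> np.ndarray | None:
        """Class probabilities where the family provides them (ANN, RF)."""
        if self.spec.kind not in ("ann", "rf"):
            return None
        Xt = self._transform(np.asarray(X, dtype=float))
        return self.estimator.predict_proba(Xt)


@dataclass
class EvalReport:
    """Accuracy (percent) with the confusion matrix it was computed from."""

    accuracy: float
    confusion: np.ndarray  # (C, C) counts, rows = true class
    classes: tuple[int, ...]
    spec_name: str

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
            "classifier": self.spec_name,
        }


def _build_estimator(spec: ClassifierSpec):
    if spec.kind == "ann":
        return MLPClassifier(
            hidden_layer_sizes=(spec.nu,) * spec.nl,
            activation="tanh",
            solver="adam",
            max_iter=800,
            early_stopping=True,
            validation_fraction=0.15,
            n_iter_no_change=40,
            random_state=spec.seed,
        )
    if spec.kind in ("msvm", "pca_msvm"):
        # One-vs-one linear SVM; libsvm is deterministic on fixed data.
        return SVC(kernel="linear", C=1.0, decision_function_shape="ovo")
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            criterion="gini",
            bootstrap=True,
            random_state=spec.seed,
        )
    raise ValueError(spec.kind)


def pca_project(train_features: np.ndarray, nv: int) -> tuple[PCA, np.ndarray]:
    """Fit a PCA map on training features only; return (map, projected)."""
    X = np.asarray(train_features, dtype=float)
    max_rank = min(X.shape)
    if nv < 1:
        raise ValueError("nv must be >= 1")
    if nv > max_rank:
        raise ValueError(f"nv={nv} exceeds feasible rank {max_rank}")
    pca = PCA(n_components=nv, svd_solver="full", whiten=False)
    return pca, pca.fit_transform(X)


def train(spec: ClassifierSpec, train_ds: Dataset, seed: int | None = None) -> FittedModel:
    """Fit one classifier on a dataset; seed overrides the spec's seed."""
    if seed is not None:
        spec = spec.with_seed(seed)
    X = train_ds.feature_matrix()
    y = train_ds.labels()
    present = np.unique(y)
    if present.size < 2:
        raise ValueError("training requires at least 2 classes present")
    counts = {c: int((y == c).sum()) for c in present}
    if min(counts.values()) < 1:
        raise ValueError("every present class needs at least one trial")

    scaler = None
    if spec.standardize:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)

    pca = None
    if spec.kind == "pca_msvm":
        pca, X = pca_project(X, spec.nv)

    est = _build_estimator(spec)
    est.fit(X, y)
    return FittedModel(
        spec=spec,
        estimator=est,
        classes=tuple(int(c) for c in train_ds.classes),
        n_features=train_ds.layout.n_features,
        scaler=scaler,
        pca=pca,
    )


def evaluate(model: FittedModel, test_ds: Dataset) -> EvalReport:
    """Score on held-out trials: percent accuracy + true-by-predicted counts."""
    if len(test_ds) == 0:
        raise ValueError("test dataset is empty")
    X = test_ds.feature_matrix()
    y_true = test_ds.labels()
    y_pred = model.predict(X)
    labels = list(model.classes)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    accuracy = 100.0 * np.trace(cm) / cm.sum()
    return EvalReport(
        accuracy=float(accuracy),
        confusion=cm,
        classes=tuple(labels),
        spec_name=model.spec.name,
    )
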