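"""Cell-type classification of catalogued nuclei.

A three-way support-vector machine assigns each nucleus to cancer, stromal
or lymphocyte from its 8-value nuclear feature vector.  Features are
standardised by training-set statistics; the RBF kernel's C and gamma are
chosen by stratified 5-fold cross-validated grid search over a fixed
logarithmic grid, with a fixed fold seed so the same data and seed always
pick the same hyperparameters.  Objects with non-finite features are
labelled ``unclassified`` and excluded from evaluation metrics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .segmentation import CLASS_LABELS, FEATURE_NAMES, UNCLASSIFIED, ObjectCatalogue

MODEL_FORMAT_VERSION = 1

C_GRID = tuple(10.0 ** e for e in range(-1, 4))       # 0.1 .. 1000
GAMMA_GRID = tuple(10.0 ** e for e in range(-3, 2))   # 0.001 .. 10


@dataclass
class TrainingSet:
    """Labelled feature vectors for classifier training."""

    features: np.ndarray  # (n, 8)
    labels: np.ndarray    # (n,) strings

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.ndim != 2 or len(self.features) != len(self.labels):
            raise ValueError("features must be (n, d) aligned with labels")
        if not np.isfinite(self.features).all():
            raise ValueError("training features must be finite")

    @property
    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrainingSet":
        df = pd.read_csv(path)
        feat_cols = [f"f{i + 1}" for i in range(len(FEATURE_NAMES))]
        return cls(df[feat_cols].to_numpy(), df["label"].to_numpy())


@dataclass
class ClassifierModel:
    """A trained standardise-then-SVM pipeline plus its provenance."""

    pipeline: Pipeline
    classes: tuple[str, ...]
    best_params: dict
    seed: int
    config_hash: str
    version: int = MODEL_FORMAT_VERSION

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=np.float64)
        if features.ndim != 2 or features.shape[1] != self.pipeline.n_features_in_:
            raise ValueError(
                f"expected (n, {self.pipeline.n_features_in_}) features, got {features.shape}"
            )
        out = np.full(len(features), UNCLASSIFIED, dtype=object)
        finite = np.isfinite(features).all(axis=1)
        if finite.any():
            out[finite] = self.pipeline.predict(features[finite])
        return out

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        return self.pipeline.decision_function(np.asarray(features, dtype=np.float64))

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        model = joblib.load(path)
        if not isinstance(model, cls) or model.version != MODEL_FORMAT_VERSION:
            raise ValueError("unrecognised classifier model file")
        return model


def train_classifier(
    ts: TrainingSet,
    seed: int = 0,
    required_classes: tuple[str, ...] = CLASS_LABELS,
    min_per_class: int = 50,
    c_grid: tuple[float, ...] = C_GRID,
    gamma_grid: tuple[float, ...] = GAMMA_GRID,
) -> ClassifierModel:
    """Fit the RBF-SVM with 5-fold cross-validated hyperparameter search."""
    counts = ts.class_counts
    for cls_name in required_classes:
        if counts.get(cls_name, 0) == 0:
            raise ValueError(f"training set is missing class {cls_name!r}")
        if counts[cls_name] < min_per_class:
            raise ValueError(
                f"class {cls_name!r} has {counts[cls_name]} examples, needs >= {min_per_class}"
            )

    pipe = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="rbf", decision_function_shape="ovo"))]
    )
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    search = GridSearchCV(
        pipe,
        {"svm__C": list(c_grid), "svm__gamma": list(gamma_grid)},
        cv=cv,
        n_jobs=1,
    )
    search.fit(ts.features, ts.labels.astype(str))

    cfg = {
        "C_grid": list(c_grid),
        "gamma_grid": list(gamma_grid),
        "seed": seed,
        "best": search.best_params_,
    }
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    return ClassifierModel(
        pipeline=search.best_estimator_,
        classes=tuple(search.best_estimator_.named_steps["svm"].classes_.tolist()),
        best_params=dict(search.best_params_),
        seed=seed,
        config_hash=cfg_hash,
    )


def classify_catalogue(model: ClassifierModel, cat: ObjectCatalogue) -> ObjectCatalogue:
    """Label every object in a catalogue; empty catalogues pass through."""
    if len(cat) == 0:
        return cat
    feats = np.array([o.features for o in cat.objects], dtype=np.float64)
    labels = model.predict(feats)
    return cat.with_labels([str(l) for l in labels])


def evaluate_classifier(model: ClassifierModel, features: np.ndarray, labels) -> dict:
    """Holdout evaluation: per-class precision/recall and the confusion
    matrix (rows = true class, columns = predicted).  Rows with non-finite
    features are excluded and counted."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    if len(features) == 0:
        raise ValueError("empty holdout")
    finite = np.isfinite(features).all(axis=1)
    pred = model.predict(features[finite])
    true = labels[finite].astype(str)

    classes = list(model.classes)
    cm = confusion_matrix(true, pred.astype(str), labels=classes)
    precision, recall = {}, {}
    for i, c in enumerate(classes):
        col = cm[:, i].sum()
        row = cm[i, :].sum()
        precision[c] = float(cm[i, i] / col) if col else float("nan")
        recall[c] = float(cm[i, i] / row) if row else float("nan")
    return {
        "classes": classes,
        "confusion": cm,
        "precision": precision,
        "recall": recall,
        "accuracy": float((pred.astype(str) == true).mean()),
        "n_excluded_nonfinite": int((~finite).sum()),
    }
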