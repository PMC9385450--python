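"""Damage-class prediction from comet feature tables.

Comets are conventionally scored into five damage classes (1 = no visible
tail ... 5 = nearly all DNA in the tail), but class labels here are opaque
positive integers, so finer sub-class schemes work unchanged. Four
classical algorithm families are provided — decision tree, k-nearest
neighbours, Gaussian naive Bayes and an RBF-kernel SVM — each behind the
same train/predict surface, with features z-scored using statistics stored
in the fitted model.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import SchemaError
from .features import FEATURE_NAMES

__all__ = [
    "ALGORITHMS",
    "ClassifierModel",
    "train_classifier",
    "predict",
    "predict_scores",
    "class_statistics",
    "save_model",
    "load_model",
]

#: Canonical algorithm names (plus short aliases accepted by the CLI).
ALGORITHMS = ("decision_tree", "knn", "naive_bayes", "svm")
_ALIASES = {"tree": "decision_tree", "nb": "naive_bayes",
            "kNN": "knn", "dt": "decision_tree"}

MODEL_FORMAT_VERSION = "1"


def _make_estimator(algorithm: str, hyperparams: dict, seed: int):
    hp = dict(hyperparams or {})
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(criterion=hp.pop("criterion", "gini"),
                                      random_state=seed, **hp)
    if algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 5), **hp)
    if algorithm == "naive_bayes":
        return GaussianNB(**hp)
    if algorithm == "svm":
        return SVC(kernel=hp.pop("kernel", "rbf"),
                   decision_function_shape="ovo",
                   random_state=seed, **hp)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class ClassifierModel:
    """A fitted comet classifier with its feature schema and seed."""

    algorithm: str
    pipeline: Pipeline
    feature_names: list[str]
    classes: np.ndarray
    seed: int
    format_version: str = MODEL_FORMAT_VERSION
    hyperparams: dict = field(default_factory=dict)


def _feature_matrix(table: pd.DataFrame, feature_names: list[str]) -> np.ndarray:
    missing = [c for c in feature_names if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns: {missing}")
    X = table[feature_names].to_numpy(dtype=np.float64)
    bad = np.flatnonzero(~np.isfinite(X).all(axis=1))
    if bad.size:
        ids = (table["comet_id"].iloc[bad].tolist()
               if "comet_id" in table.columns else bad.tolist())
        raise SchemaError(f"non-finite feature values for comets {ids}")
    return X


def train_classifier(table: pd.DataFrame, algorithm: str = "decision_tree",
                     label_col: str = "class",
                     feature_names: list[str] | None = None,
                     hyperparams: dict | None = None,
                     seed: int = 0) -> ClassifierModel:
    """Fit a classifier on a labelled feature table.

    ``feature_names`` acts as an explicit feature include-list (defaults to
    the 21 standard features present in the table). Requires at least two
    classes with at least two examples each; deterministic given ``seed``.
    """
    algorithm = _ALIASES.get(algorithm, algorithm)
    if feature_names is None:
        feature_names = [c for c in FEATURE_NAMES if c in table.columns]
        if not feature_names:
            raise SchemaError("table contains none of the standard feature columns")
    if label_col not in table.columns:
        raise SchemaError(f"label column {label_col!r} not in table")
    y = table[label_col].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training requires >= 2 distinct classes")
    if counts.min() < 2:
        rare = classes[counts < 2].tolist()
        raise ValueError(f"training requires >= 2 examples per class; "
                         f"classes {rare} have fewer")
    X = _feature_matrix(table, feature_names)
    pipe = Pipeline([("scale", StandardScaler()),
                     ("clf", _make_estimator(algorithm, hyperparams, seed))])
    pipe.fit(X, y)
    return ClassifierModel(algorithm=algorithm, pipeline=pipe,
                           feature_names=list(feature_names),
                           classes=classes, seed=seed,
                           hyperparams=dict(hyperparams or {}))


def predict(model: ClassifierModel, table: pd.DataFrame) -> np.ndarray:
    """Predict one class label per row; deterministic and row-equivariant."""
    if len(table) == 0:
        return np.array([], dtype=model.classes.dtype)
    X = _feature_matrix(table, model.feature_names)
    return model.pipeline.predict(X)


def predict_scores(model: ClassifierModel, table: pd.DataFrame) -> pd.DataFrame | None:
    """Per-class scores where the algorithm provides them (else ``None``).

    Probabilities for tree/kNN/naive Bayes; the SVM (fitted without
    probability calibration) returns ``None``.
    """
    if len(table) == 0:
        return pd.DataFrame(columns=[str(c) for c in model.classes])
    est = model.pipeline.named_steps["clf"]
    if not hasattr(est, "predict_proba"):
        return None
    X = _feature_matrix(table, model.feature_names)
    proba = model.pipeline.predict_proba(X)
    return pd.DataFrame(proba, columns=[str(c) for c in model.classes])


def class_statistics(labels) -> dict:
    """Counts and fractions per class; fractions sum to 1 for nonempty input."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return {"counts": {}, "fractions": {}, "n": 0}
    classes, counts = np.unique(labels, return_counts=True)
    n = int(counts.sum())
    return {"counts": {int(c): int(k) for c, k in zip(classes, counts)},
            "fractions": {int(c): k / n for c, k in zip(classes, counts)},
            "n": n}


def save_model(model: ClassifierModel, path: str | Path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> ClassifierModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if getattr(model, "format_version", None) != MODEL_FORMAT_VERSION:
        raise SchemaError(f"unsupported model format version in {path}")
    return model
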