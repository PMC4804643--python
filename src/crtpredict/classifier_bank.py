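"""Uniform train/predict contract over the seven binary classifiers.

The bank covers ``svm`` (linear-kernel SVC), ``rf`` (500-tree random forest),
``en`` (elastic-net-penalized logistic regression with internal CV over the
penalty strength), ``lda`` (pooled-covariance linear discriminant), and
``knn1``/``knn3``/``knn5`` (Euclidean k-nearest-neighbor).  Hyperparameters
live in ``ALGORITHM_DEFAULTS`` and can be overridden per call.

Fitted models serialize to a versioned, self-describing JSON envelope (the
sklearn estimator state is embedded as base64-encoded pickle bytes) so the
artifact files are plain text.
"""

from __future__ import annotations

import base64
import json
import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .cohort_io import CohortDataset, ExpressionMatrix
from .errors import AlgorithmError, FeatureError, TrainError
from .feature_scoring import BinaryContrast

ALGORITHMS = ("svm", "rf", "en", "lda", "knn1", "knn3", "knn5")

MODEL_FORMAT = "crtpredict-binary-model"
MODEL_FORMAT_VERSION = 1

ALGORITHM_DEFAULTS = {
    "svm": {"C": 1.0},
    "rf": {"n_estimators": 500},
    "en": {"l1_ratio": 0.5, "n_alphas": 5, "inner_folds": 5, "max_iter": 5000},
    "lda": {},
    "knn1": {},
    "knn3": {},
    "knn5": {},
}


def _make_estimator(algorithm: str, seed: int, n_per_class: int, params: dict):
    """Instantiate the sklearn estimator for one algorithm id."""
    if algorithm == "svm":
        return SVC(kernel="linear", C=params["C"], random_state=seed)
    if algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=params["n_estimators"],
            max_features="sqrt",
            random_state=seed,
        )
    if algorithm == "en":
        inner = min(params["inner_folds"], n_per_class)
        if inner >= 2:
            return LogisticRegressionCV(
                solver="saga",
                l1_ratios=[params["l1_ratio"]],
                Cs=params["n_alphas"],
                cv=StratifiedKFold(n_splits=inner, shuffle=True, random_state=seed),
                scoring="accuracy",
                max_iter=params["max_iter"],
                random_state=seed,
            )
        # too few samples for internal CV: fall back to a fixed penalty
        return LogisticRegression(
            solver="saga",
            l1_ratio=params["l1_ratio"],
            C=1.0,
            max_iter=params["max_iter"],
            random_state=seed,
        )
    if algorithm == "lda":
        return LinearDiscriminantAnalysis(solver="svd")
    if algorithm in ("knn1", "knn3", "knn5"):
        k = int(algorithm[-1])
        return KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    raise AlgorithmError(
        f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}"
    )


@dataclass
class TrainedBinaryModel:
    """A fitted one-vs-rest classifier restricted to a feature subspace."""

    algorithm: str
    feature_genes: tuple[str, ...]
    contrast: BinaryContrast
    estimator: object
    training_seed: int
    fs_type: str | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise AlgorithmError(f"unknown algorithm {self.algorithm!r}")
        if not self.feature_genes:
            raise FeatureError("model has no feature genes")
        if len(set(self.feature_genes)) != len(self.feature_genes):
            raise FeatureError("duplicate feature genes")


def _feature_matrix(expr: ExpressionMatrix, genes: Sequence[str]) -> np.ndarray:
    """Samples x features design matrix; missing genes raise FeatureError."""
    try:
        idx = expr.gene_index(genes)
    except KeyError as exc:
        missing = [g for g in genes if g not in set(expr.gene_ids)]
        raise FeatureError(f"feature genes absent from matrix: {missing}") from exc
    return expr.values[idx, :].T


def train_binary(
    cohort: CohortDataset,
    contrast: BinaryContrast,
    features: Sequence[str],
    algorithm: str,
    seed: int = 0,
    fs_type: str | None = None,
    params: dict | None = None,
) -> TrainedBinaryModel:
    """Fit one binary one-vs-rest classifier on the given feature genes.

    Deterministic given ``seed``.  Raises :class:`TrainError` if only one
    class is present, :class:`FeatureError` for absent genes and
    :class:`AlgorithmError` for an unknown algorithm id.
    """
    if algorithm not in ALGORITHMS:
        raise AlgorithmError(
            f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}"
        )
    X = _feature_matrix(cohort.expression, features)
    y = cohort.binary_response(contrast.target_class).astype(int)
    if len(np.unique(y)) < 2:
        raise TrainError(
            f"training set contains a single class for {contrast.contrast_name}"
        )
    merged = dict(ALGORITHM_DEFAULTS[algorithm])
    if params:
        merged.update(params)
    n_per_class = int(min(np.bincount(y)))
    est = _make_estimator(algorithm, seed, n_per_class, merged)
    est.fit(X, y)
    return TrainedBinaryModel(
        algorithm=algorithm,
        feature_genes=tuple(features),
        contrast=contrast,
        estimator=est,
        training_seed=seed,
        fs_type=fs_type,
    )


def predict_binary(model: TrainedBinaryModel, expr: ExpressionMatrix) -> list[str]:
    """Hard labels per sample: the target class name or ``"other"``."""
    X = _feature_matrix(expr, model.feature_genes)
    pred = np.asarray(model.estimator.predict(X)).astype(int)
    target = model.contrast.target_class
    return [target if p == 1 else "other" for p in pred]


def save_model(model: TrainedBinaryModel, path: str | Path) -> None:
    """Serialize to the versioned JSON envelope (text file)."""
    payload = model_to_dict(model)
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_model(path: str | Path) -> TrainedBinaryModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return model_from_dict(payload)


def model_to_dict(model: TrainedBinaryModel) -> dict:
    return {
        "format": MODEL_FORMAT,
        "version": MODEL_FORMAT_VERSION,
        "algorithm": model.algorithm,
        "target_class": model.contrast.target_class,
        "feature_genes": list(model.feature_genes),
        "fs_type": model.fs_type,
        "training_seed": model.training_seed,
        "estimator_pickle_b64": base64.b64encode(
            pickle.dumps(model.estimator)
        ).decode("ascii"),
    }


def model_from_dict(payload: dict) -> TrainedBinaryModel:
    if payload.get("format") != MODEL_FORMAT:
        raise AlgorithmError(f"not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise AlgorithmError(
            f"unsupported model format version {payload.get('version')}"
        )
    estimator = pickle.loads(base64.b64decode(payload["estimator_pickle_b64"]))
    return TrainedBinaryModel(
        algorithm=payload["algorithm"],
        feature_genes=tuple(payload["feature_genes"]),
        contrast=BinaryContrast(payload["target_class"]),
        estimator=estimator,
        training_seed=int(payload["training_seed"]),
        fs_type=payload.get("fs_type"),
    )
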