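"""Cross-validated grid search over feature score x feature count x algorithm.

Two scoring modes are exposed.  In ``paper`` mode the feature table is
computed once on the full cohort before cross-validation, which reuses the
test folds for feature selection and therefore gives an optimistically biased
accuracy estimate; ``nested`` mode recomputes feature scores inside each
training split.  Both are kept because the bias of the first is a documented
property the suite checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifier_bank import ALGORITHMS, predict_binary, train_binary
from .cohort_io import CohortDataset
from .errors import FoldError, SelectionError
from .feature_scoring import (
    FS_TYPES,
    BinaryContrast,
    compute_feature_table,
    select_top_k,
)

logger = logging.getLogger(__name__)

SCORING_MODES = ("paper", "nested")

# Tie-break preference when two grid cells reach the same accuracy at the
# same feature count.
ALGORITHM_PRIORITY = ("svm", "en", "rf", "lda", "knn1", "knn3", "knn5")


@dataclass(frozen=True)
class GridSpec:
    """Configuration of one grid run for a single contrast."""

    fs_types: tuple[str, ...] = FS_TYPES
    feature_counts: tuple[int, ...] = tuple(range(2, 101))
    algorithms: tuple[str, ...] = ALGORITHMS
    n_folds: int = 5
    seed: int = 0
    scoring_mode: str = "paper"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise SelectionError("n_folds must be >= 2")
        if not self.fs_types or any(f not in FS_TYPES for f in self.fs_types):
            raise SelectionError(f"fs_types must be a subset of {FS_TYPES}")
        if not self.algorithms or any(a not in ALGORITHMS for a in self.algorithms):
            raise SelectionError(f"algorithms must be a subset of {ALGORITHMS}")
        if not self.feature_counts or any(k < 1 for k in self.feature_counts):
            raise SelectionError("feature_counts must be positive")
        if self.scoring_mode not in SCORING_MODES:
            raise SelectionError(f"scoring_mode must be one of {SCORING_MODES}")


@dataclass
class GridResult:
    """Per-cell CV accuracies for one contrast."""

    contrast: BinaryContrast
    cells: dict[tuple[str, int, str], float] = field(default_factory=dict)

    def mean_accuracy(self) -> dict[tuple[str, str], float]:
        """Arithmetic mean of cell accuracies over feature counts,
        per (fs_type, algorithm) — the summary layout of the per-algorithm
        average-accuracy table."""
        groups: dict[tuple[str, str], list[float]] = {}
        for (fs, _k, alg), acc in self.cells.items():
            groups.setdefault((fs, alg), []).append(acc)
        return {key: float(np.mean(v)) for key, v in groups.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "contrast": self.contrast.contrast_name,
                "fs_type": fs,
                "k": k,
                "algorithm": alg,
                "cv_accuracy": acc,
            }
            for (fs, k, alg), acc in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)

    def mean_accuracy_frame(self) -> pd.DataFrame:
        means = self.mean_accuracy()
        fs_types = sorted({fs for fs, _ in means})
        algs = [a for a in ALGORITHM_PRIORITY if any(k[1] == a for k in means)]
        data = {
            alg: [means.get((fs, alg), np.nan) for fs in fs_types] for alg in algs
        }
        return pd.DataFrame(data, index=fs_types)


def stratified_folds(
    labels: Sequence[bool] | np.ndarray, n_folds: int, seed: int
) -> np.ndarray:
    """Fold index per sample: sizes differ by <= 1, per-class counts differ
    by <= 1 across folds, deterministic given the seed."""
    y = np.asarray(labels).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise FoldError(
            f"smallest class has {counts.min()} members, fewer than "
            f"{n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_train, test) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test] = fold
    return assignment


def cv_accuracy(
    cohort: CohortDataset,
    contrast: BinaryContrast,
    fs_type: str,
    k: int,
    algorithm: str,
    n_folds: int = 5,
    seed: int = 0,
    scoring_mode: str = "paper",
    feature_table: pd.DataFrame | None = None,
) -> float:
    """Pooled cross-validated accuracy of one grid cell.

    Every sample is predicted exactly once; accuracy is the fraction of
    correct pooled predictions.  ``feature_table`` may be passed to avoid
    recomputing whole-cohort scores in paper mode.
    """
    if scoring_mode not in SCORING_MODES:
        raise SelectionError(f"scoring_mode must be one of {SCORING_MODES}")
    y = cohort.binary_response(contrast.target_class)
    folds = stratified_folds(y, n_folds, seed)

    if scoring_mode == "paper":
        if feature_table is None:
            feature_table = compute_feature_table(cohort, contrast)
        features_global = select_top_k(feature_table, fs_type, k)

    sample_ids = np.array(cohort.expression.sample_ids)
    correct = 0
    for fold in range(n_folds):
        test_mask = folds == fold
        train_ids = sample_ids[~test_mask]
        test_ids = sample_ids[test_mask]
        train_expr = cohort.expression.subset_samples(train_ids)
        train_cohort = CohortDataset(train_expr, cohort.labels.reorder(train_ids))
        if scoring_mode == "nested":
            table = compute_feature_table(train_cohort, contrast)
            features = select_top_k(table, fs_type, k)
        else:
            features = features_global
        model = train_binary(
            train_cohort, contrast, features, algorithm, seed=seed, fs_type=fs_type
        )
        preds = predict_binary(model, cohort.expression.subset_samples(test_ids))
        truth = y[test_mask]
        pred_pos = np.array([p == contrast.target_class for p in preds])
        correct += int(np.sum(pred_pos == truth))
    return correct / len(y)


def run_grid(
    cohort: CohortDataset, contrast: BinaryContrast, spec: GridSpec
) -> GridResult:
    """Evaluate every (fs_type, k, algorithm) cell of the grid.

    One fold assignment (derived from ``spec.seed``) is shared by all cells
    of the contrast so cell accuracies are comparable.
    """
    max_k = max(spec.feature_counts)
    if max_k > cohort.expression.n_genes:
        raise SelectionError(
            f"feature count {max_k} exceeds {cohort.expression.n_genes} genes"
        )
    table = None
    if spec.scoring_mode == "paper":
        table = compute_feature_table(cohort, contrast)
    result = GridResult(contrast=contrast)
    for fs in spec.fs_types:
        for k in spec.feature_counts:
            for alg in spec.algorithms:
                acc = cv_accuracy(
                    cohort,
                    contrast,
                    fs,
                    k,
                    alg,
                    n_folds=spec.n_folds,
                    seed=spec.seed,
                    scoring_mode=spec.scoring_mode,
                    feature_table=table,
                )
                result.cells[(fs, k, alg)] = acc
                logger.debug(
                    "%s fs=%s k=%d alg=%s acc=%.4f",
                    contrast.contrast_name, fs, k, alg, acc,
                )
        logger.info(
            "%s: finished fs_type=%s (%d cells)",
            contrast.contrast_name, fs, len(spec.feature_counts) * len(spec.algorithms),
        )
    return result


def select_best(result: GridResult) -> tuple[str, int, str]:
    """Argmax cell of the grid; ties broken by smaller k, then by the fixed
    algorithm priority (svm > en > rf > lda > knn1 > knn3 > knn5)."""
    if not result.cells:
        raise SelectionError("empty grid result")
    priority = {a: i for i, a in enumerate(ALGORITHM_PRIORITY)}

    def sort_key(item):
        (fs, k, alg), acc = item
        return (-acc, k, priority[alg], fs)

    (fs, k, alg), _acc = min(result.cells.items(), key=sort_key)
    return fs, k, alg
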