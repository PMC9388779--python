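"""Responder labelling, L1-logistic classification and repeated stratified CV.

The evaluation protocol is five shuffled iterations of 10-fold stratified
("class-balanced") cross-validation; per iteration the confusion counts over
the 10 test folds are accumulated, and means with standard errors over the 5
iterations are reported for accuracy, precision, sensitivity and specificity
(responder = positive class).  Also provides the paired model comparison on
identical folds, the clinical-covariate baseline feature matrix, and the
summary-statistic utilities (pooled two-sample t, Yates-corrected chi2) used
for the demographic table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .types import SubjectRecord

__all__ = [
    "ResponderLabel",
    "LinearModel",
    "FoldRecord",
    "CVResult",
    "label_responder",
    "fit_l1_logistic",
    "default_model_factory",
    "cross_validate",
    "compare_models_paired_t",
    "clinical_baseline_features",
    "CLINICAL_FEATURE_COLUMNS",
    "two_sample_t_from_summary",
    "yates_chi2",
]

RESPONDER_THRESHOLD_PCT = 25.0


@dataclass(frozen=True)
class ResponderLabel:
    pre_score: float
    post_score: float
    percent_improvement: float
    is_responder: bool


@dataclass
class LinearModel:
    """Fitted linear classifier in original feature units."""

    weights: np.ndarray
    intercept: float
    regularization_strength: float = 1.0

    def margin(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.margin(X) >= 0).astype(int)


def label_responder(pre: float, post: float) -> ResponderLabel:
    """Responder iff PSYRATS-AH improved by at least 25% (inclusive)."""
    if pre <= 0:
        raise ValueError("pre-treatment score must be positive")
    if post < 0:
        raise ValueError("post-treatment score must be non-negative")
    pct = 100.0 * (pre - post) / pre
    return ResponderLabel(pre, post, pct, pct >= RESPONDER_THRESHOLD_PCT)


def fit_l1_logistic(
    X: np.ndarray, y: np.ndarray, strength: float = 1.0
) -> LinearModel:
    """L1-penalized logistic regression at the library-default inverse
    penalty (C = 1.0 unless overridden)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    clf = LogisticRegression(
        l1_ratio=1.0, C=strength, solver="liblinear", random_state=0
    )
    clf.fit(X, y)
    return LinearModel(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        regularization_strength=strength,
    )


def default_model_factory(strength: float = 1.0) -> Callable[[], Pipeline]:
    """Standardize (train-fold mean/SD) then L1-logistic — the default
    classifier used throughout."""

    def factory() -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    LogisticRegression(
                        l1_ratio=1.0, C=strength, solver="liblinear", random_state=0
                    ),
                ),
            ]
        )

    return factory


@dataclass
class FoldRecord:
    iteration: int
    fold: int
    test_indices: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray

    @property
    def accuracy(self) -> float:
        return float((self.y_true == self.y_pred).mean())


@dataclass
class CVResult:
    folds: list[FoldRecord]
    n_iterations: int
    n_folds: int
    n_subjects: int
    seed: int
    models: Optional[list] = None

    def iteration_confusion(self, iteration: int) -> dict[str, int]:
        tp = tn = fp = fn = 0
        for f in self.folds:
            if f.iteration != iteration:
                continue
            tp += int(((f.y_true == 1) & (f.y_pred == 1)).sum())
            tn += int(((f.y_true == 0) & (f.y_pred == 0)).sum())
            fp += int(((f.y_true == 0) & (f.y_pred == 1)).sum())
            fn += int(((f.y_true == 1) & (f.y_pred == 0)).sum())
        return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}

    def fold_accuracies(self) -> np.ndarray:
        """Per-fold test accuracies in (iteration, fold) order — the pairing
        unit for model comparison."""
        return np.array([f.accuracy for f in self.folds])

    def summary(self) -> pd.DataFrame:
        """Mean (SE over the 5 iterations) of each metric, as percentages,
        plus mean confusion counts, in a mean-(SE) results-table layout.  Accuracy is the mean of per-fold accuracies (primary); the
        pooled-count variant is reported alongside as accuracy_pooled.
        """
        rows = []
        for it in range(self.n_iterations):
            c = self.iteration_confusion(it)
            tp, tn, fp, fn = c["TP"], c["TN"], c["FP"], c["FN"]
            n = tp + tn + fp + fn
            fold_acc = [f.accuracy for f in self.folds if f.iteration == it]
            rows.append(
                {
                    "accuracy": 100.0 * float(np.mean(fold_acc)),
                    "accuracy_pooled": 100.0 * (tp + tn) / n,
                    "precision": 100.0 * tp / (tp + fp) if tp + fp else np.nan,
                    "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else np.nan,
                    "specificity": 100.0 * tn / (tn + fp) if tn + fp else np.nan,
                    "TP": tp,
                    "TN": tn,
                    "FP": fp,
                    "FN": fn,
                }
            )
        per_iter = pd.DataFrame(rows)
        mean = per_iter.mean()
        se = per_iter.std(ddof=1) / math.sqrt(len(per_iter))
        return pd.DataFrame({"mean": mean, "se": se})


def cross_validate(
    model_factory: Callable[[], object],
    X: np.ndarray,
    y: np.ndarray,
    n_iterations: int = 5,
    n_folds: int = 10,
    seed: int = 0,
    keep_models: bool = False,
) -> CVResult:
    """Repeated stratified K-fold CV with recorded fold assignments.

    Each iteration reshuffles (seeded) and stratifies folds so each fold's
    class ratio matches the cohort's within one subject; a second model
    evaluated with the same ``seed`` sees identical folds, enabling paired
    comparison.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds cohort size {n}")
    folds: list[FoldRecord] = []
    models: list = []
    for it in range(n_iterations):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + it)
        for k, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            model = model_factory()
            model.fit(X[train_idx], y[train_idx])
            pred = np.asarray(model.predict(X[test_idx])).astype(int)
            folds.append(
                FoldRecord(
                    iteration=it,
                    fold=k,
                    test_indices=test_idx.copy(),
                    y_true=y[test_idx].copy(),
                    y_pred=pred,
                )
            )
            if keep_models:
                models.append((model, train_idx.copy(), test_idx.copy()))
    return CVResult(
        folds=folds,
        n_iterations=n_iterations,
        n_folds=n_folds,
        n_subjects=n,
        seed=seed,
        models=models if keep_models else None,
    )


def compare_models_paired_t(result_a: CVResult, result_b: CVResult):
    """Two-tailed paired t-test on per-fold test accuracies.

    Requires both results to have been evaluated on identical fold
    assignments (same seed / cohort).
    """
    if len(result_a.folds) != len(result_b.folds):
        raise ValueError("fold counts differ; pairing undefined")
    for fa, fb in zip(result_a.folds, result_b.folds):
        if not np.array_equal(fa.test_indices, fb.test_indices):
            raise ValueError("fold assignments differ; pairing undefined")
    a = result_a.fold_accuracies()
    b = result_b.fold_accuracies()
    if np.allclose(a, b):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


CLINICAL_FEATURE_COLUMNS = [
    "age",
    "sex",
    "education_years",
    "duration_untreated_months",
    "duration_illness_months",
    "olanzapine_equiv",
    "pre_saps",
    "pre_sans",
    "pre_madrs",
    "pre_psyrats",
]


def clinical_baseline_features(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Baseline demographic/clinical covariate matrix with mean imputation.

    Columns follow ``CLINICAL_FEATURE_COLUMNS``; missing entries (nan) are
    replaced by the mean of the observed values in that column.
    """
    df = pd.DataFrame(
        [{c: getattr(r, c) for c in CLINICAL_FEATURE_COLUMNS} for r in records]
    )
    for col in df.columns:
        if df[col].isna().all():
            raise ValueError(f"column {col!r} has no observed values to impute from")
        if df[col].isna().any():
            df[col] = df[col].fillna(df[col].mean())
    return df


def two_sample_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    """Pooled-variance two-sample t from printed group summaries."""
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    denom = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if denom == 0:
        return 0.0 if m1 == m2 else math.inf * (1 if m1 > m2 else -1)
    return (m1 - m2) / denom


def yates_chi2(table: np.ndarray) -> float:
    """Continuity-corrected chi-square on a 2x2 table.

    chi2 = sum (|O - E| - 0.5)^2 / E, with the correction floored at zero
    when |O - E| < 0.5.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin")
    expected = row @ col / total
    corrected = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    return float((corrected**2 / expected).sum())
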