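"""Scoring of imputation accuracy and differential-expression calls.

Imputation accuracy is the non-normalized root mean squared error over the
S x G imputed cells,

    RMSE = sqrt( (1/(S G)) sum_i sum_j (x_ij - xhat_ij)^2 ),

and DE calling is summarized by TPR = TP/(TP+FN), FPR = FP/(FP+TN) and the
empirical false discovery proportion FDR = FP/(TP+FP) (defined as 0 when no
calls are made). A column-mean imputation baseline is included for RMSE
comparisons.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import PairedExpressionSet, ValidationError

__all__ = ["ConfusionMetrics", "rmse", "confusion_metrics", "mean_impute"]


@dataclasses.dataclass
class ConfusionMetrics:
    tpr: float  # NaN when the truth has no positives
    fpr: float  # NaN when the truth has no negatives
    fdr: float


def rmse(true_rows: np.ndarray, imputed_rows: np.ndarray) -> float:
    """Non-normalized RMSE between true and imputed values."""
    t = np.asarray(true_rows, float)
    h = np.asarray(imputed_rows, float)
    if t.shape != h.shape:
        raise ValidationError(f"shape mismatch: {t.shape} vs {h.shape}")
    if t.size == 0:
        raise ValidationError("RMSE of an empty selection is undefined")
    return float(np.sqrt(np.mean((t - h) ** 2)))


def confusion_metrics(called: np.ndarray, truth: np.ndarray) -> ConfusionMetrics:
    """TPR/FPR/FDR of boolean DE calls against ground truth.

    TPR is NaN (not 0) when the truth contains no positives, FPR is NaN when
    it contains no negatives; FDR is 0 when no calls are made.
    """
    called = np.asarray(called, bool)
    truth = np.asarray(truth, bool)
    if called.shape != truth.shape:
        raise ValidationError(f"length mismatch: {called.shape} vs {truth.shape}")
    tp = int((called & truth).sum())
    fp = int((called & ~truth).sum())
    fn = int((~called & truth).sum())
    tn = int((~called & ~truth).sum())
    tpr = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    fpr = fp / (fp + tn) if (fp + tn) > 0 else float("nan")
    fdr = fp / (tp + fp) if (tp + fp) > 0 else 0.0
    return ConfusionMetrics(tpr=tpr, fpr=fpr, fdr=fdr)


def mean_impute(pes: PairedExpressionSet) -> np.ndarray:
    """Column-mean baseline: fill missing normal rows with per-feature
    means over the observed normal samples."""
    if pes.n_missing == pes.n_subjects:
        raise ValidationError("no observed normal rows to average")
    completed = pes.normal.copy()
    col_means = pes.normal[pes.observed_idx].mean(axis=0)
    completed[pes.missing_idx] = col_means
    return completed
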