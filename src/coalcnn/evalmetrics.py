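"""Evaluation metrics: RMSE, R-squared, Spearman correlation, row-normalized
confusion matrices, exact binomial confidence intervals, and the lowess
paired-comparison curve used to compare two estimators along the truth axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "EvalReport", "rmse", "r_squared", "spearman_rho", "confusion",
    "accuracy_ci", "paired_better_curve",
]


def rmse(truth: np.ndarray, pred: np.ndarray) -> float:
    """Root-mean-square error pooled over every element (all output dims)."""
    truth = np.asarray(truth, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    if truth.size == 0:
        raise ValueError("rmse requires at least one value")
    return float(np.sqrt(np.mean((truth - pred) ** 2)))


def r_squared(truth: np.ndarray, pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot about the truth mean.

    This is not the squared Pearson correlation: a biased predictor can
    score lower even when strongly correlated with the truth.
    """
    truth = np.asarray(truth, dtype=np.float64).ravel()
    pred = np.asarray(pred, dtype=np.float64).ravel()
    if truth.shape != pred.shape:
        raise ValueError("shape mismatch")
    if truth.size < 2:
        raise ValueError("r_squared requires n >= 2")
    ss_tot = np.sum((truth - truth.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("r_squared undefined for constant truth")
    return float(1.0 - np.sum((truth - pred) ** 2) / ss_tot)


def spearman_rho(truth: np.ndarray, pred: np.ndarray):
    """Spearman rank correlation (average ranks for ties), per output dim.

    Returns a float for 1-D inputs, else one value per column.
    """
    truth = np.asarray(truth, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if truth.shape != pred.shape:
        raise ValueError("shape mismatch")
    if truth.shape[0] < 3:
        raise ValueError("spearman_rho requires n >= 3")
    if truth.ndim == 1:
        return float(stats.spearmanr(truth, pred).statistic)
    return np.array([
        stats.spearmanr(truth[:, j], pred[:, j]).statistic
        for j in range(truth.shape[1])
    ])


def confusion(truth_labels, pred_labels, k: int) -> tuple[np.ndarray, float]:
    """Row-normalized confusion matrix and overall accuracy.

    Entry (y, x) is the fraction of true-class-y examples predicted as x;
    rows for classes absent from the truth are left as zeros.
    """
    truth_labels = np.asarray(truth_labels, dtype=np.int64)
    pred_labels = np.asarray(pred_labels, dtype=np.int64)
    if truth_labels.shape != pred_labels.shape:
        raise ValueError("shape mismatch")
    if truth_labels.size and (
        truth_labels.min() < 0 or truth_labels.max() >= k
        or pred_labels.min() < 0 or pred_labels.max() >= k
    ):
        raise ValueError(f"labels must lie in 0..{k - 1}")
    counts = np.zeros((k, k), dtype=np.float64)
    np.add.at(counts, (truth_labels, pred_labels), 1.0)
    row_tot = counts.sum(axis=1, keepdims=True)
    matrix = np.divide(counts, row_tot, out=np.zeros_like(counts), where=row_tot > 0)
    accuracy = float(np.trace(counts) / truth_labels.size)
    return matrix, accuracy


def accuracy_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval, as computed by
    R's ``binom.test``."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in 0..n")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


def paired_better_curve(x: np.ndarray, wins: np.ndarray, span: float = 0.15) -> np.ndarray:
    """Lowess-smoothed probability that method A beats method B, along x.

    ``wins`` scores 1 where method A was more accurate and 0 otherwise;
    the curve is a locally weighted (tricube) regression with the given
    span and one robustness iteration, evaluated at the observed x.
    """
    x = np.asarray(x, dtype=np.float64)
    wins = np.asarray(wins, dtype=np.float64)
    if x.shape != wins.shape:
        raise ValueError("x and wins must have equal length")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    return lowess(wins, x, frac=span, it=1, return_sorted=False)


@dataclass
class EvalReport:
    """Summary of a trained model on a test set."""

    task: str
    n_test: int
    metrics: dict = field(default_factory=dict)
    confusion_matrix: np.ndarray | None = None
    accuracy_ci95: tuple[float, float] | None = None
    class_names: list[str] | None = None

    def to_dict(self) -> dict:
        d = {"task": self.task, "n_test": self.n_test, "metrics": dict(self.metrics)}
        if self.confusion_matrix is not None:
            d["confusion"] = np.asarray(self.confusion_matrix).tolist()
        if self.accuracy_ci95 is not None:
            d["accuracy_ci95"] = list(self.accuracy_ci95)
        if self.class_names is not None:
            d["class_names"] = list(self.class_names)
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def confusion_to_csv(self, path) -> None:
        if self.confusion_matrix is None:
            raise ValueError("report has no confusion matrix")
        names = self.class_names or [str(i) for i in range(len(self.confusion_matrix))]
        with open(path, "w") as fh:
            fh.write("true_class," + ",".join(names) + "\n")
            for name, row in zip(names, np.asarray(self.confusion_matrix)):
                fh.write(name + "," + ",".join(f"{v:.6f}" for v in row) + "\n")
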