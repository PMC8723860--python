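"""Diagnostic performance metrics for binary CKD classification.

All metrics derive from the confusion counts (TP, FN, TN, FP) with the
disease class as positive:

    sensitivity = TP / (TP + FN)          true-positive rate
    specificity = TN / (TN + FP)          true-negative rate
    accuracy    = (TP + TN) / n
    F-score     = harmonic mean of precision and sensitivity
    kappa       = (p_o - p_e) / (1 - p_e)  (Cohen; p_e from marginals)

AUC is computed by the rank (Mann–Whitney) method over the positive-class
scores, equivalent to the trapezoidal area under the ROC curve with tie
handling by mid-ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

METRIC_COLUMNS = ("Sensitivity", "Specificity", "Accuracy", "F-score", "Kappa")


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float
    f_score: float
    kappa: float
    auc: float

    def as_row(self) -> dict[str, float]:
        return {
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "Accuracy": self.accuracy,
            "F-score": self.f_score,
            "Kappa": self.kappa,
        }


def metrics_from_counts(tp: int, fn: int, tn: int, fp: int,
                        auc: float = float("nan")) -> MetricsReport:
    """Build the full report from confusion counts alone."""
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("empty confusion matrix")
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / n
    prec = tp / (tp + fp) if tp + fp else 0.0
    f = (2 * prec * sens / (prec + sens)) if prec + sens else 0.0
    p_o = acc
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 1.0
    return MetricsReport(tp=tp, fn=fn, tn=tn, fp=fp, sensitivity=sens,
                         specificity=spec, accuracy=acc, f_score=f,
                         kappa=kappa, auc=auc)


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC of the positive-class scores (ties -> mid-ranks)."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
) -> MetricsReport:
    """Full metric suite; inputs are 0/1 vectors with 1 = disease.

    ``scores`` are positive-class scores for the AUC; predictions are used
    when absent (yielding the balanced-accuracy AUC of a hard classifier).
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    auc = auc_score(y_true, y_pred if scores is None else scores)
    return metrics_from_counts(tp, fn, tn, fp, auc=auc)


def average_report(rows: list[dict[str, float]] | pd.DataFrame,
                   decimals: int = 4) -> dict[str, float]:
    """Arithmetic column means at the given display precision
    (round-half-even, matching 4-decimal reporting)."""
    df = pd.DataFrame(rows)
    return {col: round(float(df[col].mean()), decimals) for col in df.columns}


@dataclass
class RunReport:
    """Per-run metric rows plus their column-mean Average row."""

    runs: list[MetricsReport]
    meta: dict | None = None

    @property
    def average(self) -> dict[str, float]:
        return average_report([r.as_row() for r in self.runs])

    def to_dataframe(self, decimals: int = 4) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.runs, start=1):
            row = {k: round(v, decimals) for k, v in r.as_row().items()}
            rows.append({"No. of runs": f"Run-{i}", **row})
        rows.append({"No. of runs": "Average", **self.average})
        return pd.DataFrame(rows, columns=["No. of runs", *METRIC_COLUMNS])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def confusion_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"run": i + 1, "TP": r.tp, "FN": r.fn, "TN": r.tn, "FP": r.fp}
             for i, r in enumerate(self.runs)]
        )
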