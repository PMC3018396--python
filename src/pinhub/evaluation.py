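"""Evaluation of four-class hub-role predictions.

Metrics: the 4x4 confusion matrix; average correct classification rate
(CCR, the unweighted mean of per-class recalls); Pearson correlation of
the integer-coded actual and predicted labels; one-vs-rest sensitivity /
specificity / PPV / NPV per class (and for the merged PH+DH hub
super-class); ROC AUC per class from posterior scores.

Percentages are reported on the 0-100 scale; internal computation keeps
full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .io_formats import CLASS_LABELS, CLASS_NAMES

__all__ = [
    "confusion_matrix",
    "average_ccr",
    "label_correlation",
    "ovr_metrics",
    "roc_auc",
    "evaluate",
    "EvaluationReport",
]


def confusion_matrix(actual, predicted) -> np.ndarray:
    """4x4 count matrix, rows = true class (1..4), columns = predicted."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    for arr, name in ((actual, "actual"), (predicted, "predicted")):
        bad = set(np.unique(arr)) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"{name} labels outside 1..4: {sorted(bad)}")
    return _sk_confusion(actual, predicted, labels=list(CLASS_LABELS))


def average_ccr(matrix: np.ndarray) -> float:
    """Unweighted mean of the four per-class recalls, as a percentage.

    Depends only on the row-normalized matrix, so it is invariant to
    per-class sample-size rebalancing.
    """
    matrix = np.asarray(matrix, dtype=float)
    row_sums = matrix.sum(axis=1)
    if np.any(row_sums <= 0):
        empty = [CLASS_NAMES[c + 1] for c in np.flatnonzero(row_sums <= 0)]
        raise ValueError(f"empty class rows: {empty}")
    recalls = np.diag(matrix) / row_sums
    return float(recalls.mean() * 100.0)


def label_correlation(actual, predicted) -> float:
    """Pearson correlation of integer-coded labels (1=NH .. 4=DH), x100."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.std() == 0 or predicted.std() == 0:
        raise ValueError("label correlation undefined for a constant label vector")
    r, _ = pearsonr(actual, predicted)
    return float(r * 100.0)


def _binary_metrics(tp: float, fn: float, fp: float, tn: float) -> dict[str, float]:
    def ratio(num: float, den: float) -> float:
        return float(num / den * 100.0) if den > 0 else float("nan")

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def ovr_metrics(matrix: np.ndarray) -> dict[str, dict[str, float]]:
    """One-vs-rest sensitivity/specificity/PPV/NPV per class, as percentages.

    Keys are the class names NH, IC, PH, DH plus "PH+DH" for the merged
    hub super-class (both hub classes collapsed before binarization, so a
    party hub predicted as date hub still counts as a detected hub).
    Undefined ratios (zero denominator) are reported as NaN.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4):
        raise ValueError("confusion matrix must be 4x4")
    total = m.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    out: dict[str, dict[str, float]] = {}
    for c in range(4):
        tp = m[c, c]
        fn = m[c].sum() - tp
        fp = m[:, c].sum() - tp
        tn = total - tp - fn - fp
        out[CLASS_NAMES[c + 1]] = _binary_metrics(tp, fn, fp, tn)
    hub = [2, 3]
    tp = m[np.ix_(hub, hub)].sum()
    fn = m[hub, :].sum() - tp
    fp = m[:, hub].sum() - tp
    tn = total - tp - fn - fp
    out["PH+DH"] = _binary_metrics(tp, fn, fp, tn)
    return out


def roc_auc(actual, scores, positive_class: int) -> float:
    """Area under the one-vs-rest ROC curve for one class.

    Mann-Whitney (midrank) formulation: ties between positive and negative
    scores get half credit.
    """
    actual = np.asarray(actual)
    binary = (actual == positive_class).astype(int)
    if len(np.unique(binary)) < 2:
        raise ValueError(
            f"class {positive_class}: need both positives and negatives for ROC"
        )
    return float(roc_auc_score(binary, np.asarray(scores, dtype=float)))


@dataclass
class EvaluationReport:
    """Full evaluation of one prediction run."""

    confusion: np.ndarray
    average_ccr: float
    correlation: float
    per_class: dict[str, dict[str, float]]
    auc: dict[str, float] = field(default_factory=dict)

    @property
    def confusion_percent(self) -> np.ndarray:
        """Row-normalized confusion matrix in percent."""
        return self.confusion / self.confusion.sum(axis=1, keepdims=True) * 100.0

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "confusion_percent": np.round(self.confusion_percent, 1).tolist(),
            "average_ccr": round(self.average_ccr, 1),
            "correlation": None if np.isnan(self.correlation) else round(self.correlation, 1),
            "per_class": {
                k: {m: (None if np.isnan(v) else round(v, 1)) for m, v in row.items()}
                for k, row in self.per_class.items()
            },
            "auc": {k: round(v, 3) for k, v in self.auc.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"average_ccr\t{self.average_ccr:.1f}\n")
            fh.write(f"correlation\t{self.correlation:.1f}\n")
            for name, row in self.per_class.items():
                cells = "\t".join(f"{row[m]:.1f}" for m in
                                  ("sensitivity", "specificity", "ppv", "npv"))
                fh.write(f"{name}\t{cells}\n")
            for name, value in self.auc.items():
                fh.write(f"auc_{name}\t{value:.3f}\n")


def evaluate(actual, predicted, scores: np.ndarray | None = None) -> EvaluationReport:
    """Assemble the full report; ``scores`` is an optional (n, 4) posterior matrix."""
    cm = confusion_matrix(actual, predicted)
    try:
        correlation = label_correlation(actual, predicted)
    except ValueError:  # constant predictions: not computable
        correlation = float("nan")
    auc: dict[str, float] = {}
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        for c, label in enumerate(CLASS_LABELS):
            if len(np.unique(np.asarray(actual) == label)) == 2:
                auc[CLASS_NAMES[label]] = roc_auc(actual, scores[:, c], label)
    return EvaluationReport(
        confusion=cm,
        average_ccr=average_ccr(cm),
        correlation=correlation,
        per_class=ovr_metrics(cm),
        auc=auc,
    )
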