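"""Confusion matrices, one-vs-rest metrics and report generation.

Metrics follow the one-vs-rest reduction: for each target class, its
subjects are the positives and the other three classes the negatives, giving
TP / FN / FP / TN counts from the 4x4 confusion matrix and

    recall    R  = TP / (TP + FN)
    precision P  = TP / (TP + FP)
    F1           = harmonic mean of R and P  (2/F1 = 1/R + 1/P)

Overall accuracy is the confusion-matrix trace over the total count.
Reports are written in the standard benchmark-table style (label, classifier, recall,
precision, F1-score at two decimals, round-half-even) together with
loss/accuracy curves as CSV and PNG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .phantom import CLASSES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Count grid: rows are true classes, columns predicted classes."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.classes):
            raise ValueError(f"confusion matrix must be {len(self.classes)}x{len(self.classes)}")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("confusion counts must be nonnegative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def ovr_counts(self, target: int | str) -> dict:
        """One-vs-rest TP/FN/FP/TN for a target class (index or name)."""
        i = self.classes.index(target) if isinstance(target, str) else int(target)
        c = self.counts
        tp = int(c[i, i])
        fn = int(c[i, :].sum() - tp)
        fp = int(c[:, i].sum() - tp)
        tn = int(c.sum() - tp - fn - fp)
        return {"TP": tp, "FN": fn, "FP": fp, "TN": tn}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


def confusion(
    true_labels: Sequence, predicted_labels: Sequence, classes: Sequence[str] = CLASSES
) -> ConfusionMatrix:
    """Exact count grid from paired label sequences (names or indices)."""
    classes = tuple(classes)
    idx = {c: i for i, c in enumerate(classes)}

    def to_index(v):
        if isinstance(v, str):
            if v not in idx:
                raise ValueError(f"unknown label {v!r}; expected one of {classes}")
            return idx[v]
        i = int(v)
        if not 0 <= i < len(classes):
            raise ValueError(f"label index {i} out of range for {classes}")
        return i

    t = [to_index(v) for v in true_labels]
    p = [to_index(v) for v in predicted_labels]
    if len(t) != len(p):
        raise ValueError("true and predicted label sequences differ in length")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, classes)


def predict_classes(probs: np.ndarray) -> np.ndarray:
    """Argmax of softmax outputs; ties break toward the lowest class index."""
    return np.asarray(probs).argmax(axis=-1)


def per_class_metrics(cm: ConfusionMatrix, target: int | str) -> tuple[float, float, float]:
    """One-vs-rest (recall, precision, F1) for a target class.

    A metric whose denominator is zero (no true instances for recall, no
    predictions for precision) is undefined and reported as NaN with a
    logged note, never silently zero.
    """
    c = cm.ovr_counts(target)
    tp, fn, fp = c["TP"], c["FN"], c["FP"]
    name = target if isinstance(target, str) else cm.classes[int(target)]
    if tp + fn == 0:
        logger.warning("recall undefined for class %s: no true instances", name)
        recall = float("nan")
    else:
        recall = tp / (tp + fn)
    if tp + fp == 0:
        logger.warning("precision undefined for class %s: nothing predicted as it", name)
        precision = float("nan")
    else:
        precision = tp / (tp + fp)
    f1 = f1_score(recall, precision)
    return recall, precision, f1


def f1_score(recall: float, precision: float) -> float:
    """Harmonic mean 2PR/(P+R); NaN if either input is NaN, 0 if both are 0."""
    if np.isnan(recall) or np.isnan(precision):
        return float("nan")
    if recall + precision == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix has no accuracy")
    return float(np.trace(cm.counts) / cm.total)


def metrics_report(cm: ConfusionMatrix, classifier: str = "3D") -> pd.DataFrame:
    """Per-class one-vs-rest metrics table for one classifier."""
    rows = []
    for cls in cm.classes:
        r, p, f1 = per_class_metrics(cm, cls)
        rows.append({"Labels": cls, "Classifier": classifier, "Recall": r, "Precision": p, "F1-score": f1})
    return pd.DataFrame(rows)


def round2(x: float) -> float:
    """Two-decimal round-half-even, the report-table convention."""
    if isinstance(x, float) and np.isnan(x):
        return x
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def report(
    out_dir,
    metrics: pd.DataFrame,
    histories: dict | None = None,
    confusions: dict | None = None,
) -> dict:
    """Write the metrics table, confusion matrices and curve CSV/PNG files.

    ``metrics`` is a concatenation of :func:`metrics_report` frames (one per
    classifier); ``histories`` maps classifier name -> TrainingHistory and
    ``confusions`` classifier name -> ConfusionMatrix.  Metric values are
    rounded to two decimals in the written table.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    table = metrics.copy()
    for col in ("Recall", "Precision", "F1-score"):
        table[col] = table[col].map(round2)
    metrics_path = out_dir / "metrics.csv"
    table.to_csv(metrics_path, index=False)
    written["metrics"] = metrics_path

    for name, cm in (confusions or {}).items():
        p = out_dir / f"confusion_{name}.csv"
        cm.to_dataframe().to_csv(p)
        written[f"confusion_{name}"] = p

    if histories:
        frames = []
        for name, hist in histories.items():
            df = hist.to_dataframe()
            df.insert(0, "classifier", name)
            frames.append(df)
        curves = pd.concat(frames, ignore_index=True)
        curves_path = out_dir / "curves.csv"
        curves.to_csv(curves_path, index=False)
        written["curves"] = curves_path
        written["curves_png"] = _plot_curves(out_dir / "curves.png", histories)
    return written


def _plot_curves(path, histories: dict):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_loss, ax_acc) = plt.subplots(1, 2, figsize=(10, 4))
    for name, hist in histories.items():
        df = hist.to_dataframe()
        ax_loss.plot(df["epoch"], df["train_loss"], label=f"{name} train")
        ax_loss.plot(df["epoch"], df["test_loss"], "--", label=f"{name} test")
        ax_acc.plot(df["epoch"], df["train_acc"], label=f"{name} train")
        ax_acc.plot(df["epoch"], df["test_acc"], "--", label=f"{name} test")
    ax_loss.set_xlabel("epoch"), ax_loss.set_ylabel("loss"), ax_loss.legend(fontsize=7)
    ax_acc.set_xlabel("epoch"), ax_acc.set_ylabel("accuracy"), ax_acc.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
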