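"""Per-class one-vs-rest metrics, macro averages, and run comparison.

For each class ``c`` the multi-class confusion matrix is collapsed to
one-vs-rest counts TP/FP/FN/TN and the standard ratios are reported in
percent: accuracy ``(TP+TN)/N``, precision ``TP/(TP+FP)``, recall
``TP/(TP+FN)``, specificity ``TN/(TN+FP)``, and F1 ``2PR/(P+R)``, plus
the class support. A ratio with zero denominator is reported as 0 and
flagged, so macro averages (unweighted means over classes) stay defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

METRICS = ("accuracy", "precision", "recall", "specificity", "f1")


def confusion(y_true, y_pred, n_classes: int = 12) -> np.ndarray:
    """Confusion matrix with rows = true class, columns = predicted.

    Labels must be class ids in ``1..n_classes``; entry ``[i-1, j-1]``
    counts windows with true class ``i`` predicted as ``j``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        bad = np.flatnonzero((arr < 1) | (arr > n_classes))
        if bad.size:
            raise ValueError(
                f"{name}[{bad[0]}] = {arr[bad[0]]} outside valid classes 1..{n_classes}"
            )
    return _sk_confusion(y_true, y_pred, labels=np.arange(1, n_classes + 1))


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and macro metrics plus the confusion matrix.

    ``table`` has one row per class (indexed by class id) with metric
    columns in percent and a ``support`` count, plus a ``macro`` row
    holding the unweighted mean of each metric and the total support.
    ``undefined`` flags (class id, metric) pairs whose ratio had a zero
    denominator and was reported as 0.
    """

    table: pd.DataFrame
    cm: np.ndarray
    undefined: tuple[tuple[int, str], ...] = ()

    @property
    def macro(self) -> pd.Series:
        return self.table.loc["macro"]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        out = self.table.copy()
        out[list(METRICS)] = out[list(METRICS)].round(decimals)
        return out


def per_class_metrics(cm: np.ndarray) -> MetricsReport:
    """One-vs-rest metrics (percent) per class from a confusion matrix."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    C = cm.shape[0]
    N = cm.sum()
    rows = []
    undefined: list[tuple[int, str]] = []

    def ratio(num, den, class_id, name):
        if den == 0:
            undefined.append((class_id, name))
            return 0.0
        return num / den

    for i in range(C):
        cid = i + 1
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = N - tp - fn - fp
        prec = ratio(tp, tp + fp, cid, "precision")
        rec = ratio(tp, tp + fn, cid, "recall")
        f1 = ratio(2 * prec * rec, prec + rec, cid, "f1")
        rows.append(
            {
                "accuracy": 100.0 * ratio(tp + tn, N, cid, "accuracy"),
                "precision": 100.0 * prec,
                "recall": 100.0 * rec,
                "specificity": 100.0 * ratio(tn, tn + fp, cid, "specificity"),
                "f1": 100.0 * f1,
                "support": int(tp + fn),
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(range(1, C + 1), name="class"))
    macro = table[list(METRICS)].mean()
    macro["support"] = table["support"].sum()
    table.loc["macro"] = macro
    table["support"] = table["support"].astype(int)
    return MetricsReport(table=table, cm=cm, undefined=tuple(undefined))


def compare_runs(report_a: MetricsReport, report_b: MetricsReport) -> pd.DataFrame:
    """Delta report (b - a): macro deltas per metric + per-class recall deltas.

    Mirrors a side-by-side comparison of an unbalanced-training run (a)
    against a rebalanced one (b): positive deltas mean b improved.
    """
    if list(report_a.table.index) != list(report_b.table.index):
        raise ValueError("reports cover different class sets")
    rows = {
        f"macro_{m}": report_b.macro[m] - report_a.macro[m] for m in METRICS
    }
    classes = [c for c in report_a.table.index if c != "macro"]
    for c in classes:
        rows[f"recall_class_{c}"] = (
            report_b.table.loc[c, "recall"] - report_a.table.loc[c, "recall"]
        )
    return pd.DataFrame({"delta": rows})


def plot_confusion(cm: np.ndarray, path: str | Path, title: str = "Confusion matrix") -> None:
    """Heat-map rendering of a confusion matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    im = ax.imshow(cm, cmap="Blues")
    C = cm.shape[0]
    ax.set_xticks(range(C), [str(i + 1) for i in range(C)])
    ax.set_yticks(range(C), [str(i + 1) for i in range(C)])
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    ax.set_title(title)
    thresh = cm.max() / 2 if cm.max() else 0.5
    for i in range(C):
        for j in range(C):
            ax.text(
                j, i, str(cm[i, j]), ha="center", va="center",
                color="white" if cm[i, j] > thresh else "black", fontsize=7,
            )
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
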