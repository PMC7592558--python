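"""Nine-metric evaluation panel for imbalanced binary classification.

Threshold metrics (recall, specificity, precision, F1, balanced accuracy,
MCC, sensitivity-specificity gap) are computed from exact confusion counts
with explicit zero-denominator conventions; the Brier score is the mean
squared difference between predicted probability and outcome; AUROC and AUPRC
are the ranking metrics (Mann-Whitney concordance with half credit for ties,
and step-wise average precision, respectively — delegated to scikit-learn).

The composite "average of nine" subtracts the two lower-is-better members:

    average9 = (F1 + MCC + AUROC + AUPRC + BA + precision + recall
                - Brier - SSG) / 9

Accuracy and specificity are computed but excluded from the headline panel;
specificity is still reported in the supplementary-style output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricPanel",
    "confusion",
    "threshold_metrics",
    "brier",
    "auroc",
    "auprc",
    "full_panel",
    "PANEL_METRICS",
    "LOWER_IS_BETTER",
]

#: headline panel members in reporting order
PANEL_METRICS = (
    "f1",
    "mcc",
    "auroc",
    "auprc",
    "balanced_accuracy",
    "precision",
    "recall",
    "brier",
    "ssg",
)
#: members where a smaller value is better
LOWER_IS_BETTER = frozenset({"brier", "ssg"})


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.tn, self.fn)


@dataclass(frozen=True)
class MetricPanel:
    """One method x dataset evaluation cell."""

    recall: float
    specificity: float
    precision: float
    f1: float
    balanced_accuracy: float
    mcc: float
    brier: float
    auroc: float
    auprc: float
    ssg: float
    average9: float
    accuracy: float  # supplementary; excluded from the headline panel

    def to_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in PANEL_METRICS + ("average9",)}

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_dict())


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Exact confusion counts; active class is the positive class (label 1)."""
    yt = np.asarray(y_true, int)
    yp = np.asarray(y_pred, int)
    if yt.shape != yp.shape or yt.size < 1:
        raise ValueError("y_true and y_pred must be equal-length, nonempty")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def threshold_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Confusion-derived metrics with zero-denominator conventions.

    Conventions: precision = 0 when TP + FP = 0; F1 = 0 when
    precision + recall = 0; MCC = 0 when any denominator factor is 0.
    """
    tp, fp, tn, fn = (float(v) for v in c.as_tuple())
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    precision = _safe_div(tp, tp + fp)
    f1 = _safe_div(2.0 * precision * recall, precision + recall)
    ba = (recall + specificity) / 2.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = _safe_div(tp * tn - fp * fn, np.sqrt(denom)) if denom > 0 else 0.0
    return {
        "recall": recall,
        "specificity": specificity,
        "precision": precision,
        "f1": f1,
        "balanced_accuracy": ba,
        "mcc": float(mcc),
        "ssg": abs(recall - specificity),
        "accuracy": _safe_div(tp + tn, c.n),
    }


def brier(y_true, prob_active) -> float:
    """Mean squared difference between predicted probability and outcome."""
    yt = np.asarray(y_true, float)
    p = np.asarray(prob_active, float)
    if yt.shape != p.shape:
        raise ValueError("length mismatch")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - yt) ** 2))


def auroc(y_true, scores) -> float:
    """Area under the ROC curve (= Mann-Whitney concordance, ties half)."""
    yt = np.asarray(y_true, int)
    if len(np.unique(yt)) < 2:
        raise ValueError("AUROC undefined for single-class truth")
    return float(roc_auc_score(yt, np.asarray(scores, float)))


def auprc(y_true, scores) -> float:
    """Area under the precision-recall curve via step-wise average precision
    (no linear interpolation between operating points)."""
    yt = np.asarray(y_true, int)
    if (yt == 1).sum() == 0:
        raise ValueError("AUPRC undefined without positive instances")
    return float(average_precision_score(yt, np.asarray(scores, float)))


def full_panel(y_true, labels, prob_active) -> MetricPanel:
    """Populate every panel field from vote labels and ensemble probabilities."""
    c = confusion(y_true, labels)
    t = threshold_metrics(c)
    bs = brier(y_true, prob_active)
    roc = auroc(y_true, prob_active)
    prc = auprc(y_true, prob_active)
    average9 = (
        t["f1"] + t["mcc"] + roc + prc + t["balanced_accuracy"]
        + t["precision"] + t["recall"] - bs - t["ssg"]
    ) / 9.0
    return MetricPanel(
        recall=t["recall"],
        specificity=t["specificity"],
        precision=t["precision"],
        f1=t["f1"],
        balanced_accuracy=t["balanced_accuracy"],
        mcc=t["mcc"],
        brier=bs,
        auroc=roc,
        auprc=prc,
        ssg=t["ssg"],
        average9=average9,
        accuracy=t["accuracy"],
    )


def panels_to_frame(panels: dict[tuple[str, str], MetricPanel]) -> pd.DataFrame:
    """Long-format table from {(method, dataset): panel} mappings."""
    rows = []
    for (method, dataset), panel in panels.items():
        row = {"method": method, "dataset": dataset}
        row.update(panel.to_dict())
        row["specificity"] = panel.specificity
        row["accuracy"] = panel.accuracy
        rows.append(row)
    return pd.DataFrame(rows)


def panels_to_json(panels: dict[tuple[str, str], MetricPanel], path) -> None:
    """Write the long-format panel records as a JSON array."""
    import json

    records = panels_to_frame(panels).to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)
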