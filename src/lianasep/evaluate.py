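"""Imbalance-aware evaluation of liana point classification.

Liana woody points (class 1) are the positive class. Because they make up
only a few percent of a plot, accuracy and ROC curves are avoided; the
module reports precision, recall, F1, false-positive rate, the
precision-recall curve and its average-precision (AP) summary, where AP is
the recall-increment-weighted mean of precision over the distinct predicted
probabilities used as thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cloud import LIANA, OTHER, ValidationError

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion",
    "precision_recall_f1_fpr",
    "pr_curve_and_ap",
    "evaluate_predictions",
    "aggregate_reports",
    "plot_pr_curve",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts with liana woody points as positives."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvaluationReport:
    """Scalar metrics plus optional PR curve for one evaluation."""

    counts: ConfusionCounts
    precision: float
    recall: float
    f1: float
    fpr: float
    ap: float | None = None
    pr_curve: list[tuple[float, float, float]] | None = None
    #: names of metrics whose denominator was zero (value reported as 0)
    undefined: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        out = {
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "fn": self.counts.fn, "tn": self.counts.tn},
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "fpr": self.fpr,
        }
        if self.ap is not None:
            out["ap"] = self.ap
        if self.undefined:
            out["undefined"] = list(self.undefined)
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2)

    def pr_curve_to_csv(self, path) -> None:
        if self.pr_curve is None:
            raise ValidationError("report has no PR curve (no probabilities given)")
        with open(path, "w") as handle:
            handle.write("threshold,precision,recall\n")
            for thr, prec, rec in self.pr_curve:
                handle.write(f"{thr:.10g},{prec:.10g},{rec:.10g}\n")


def confusion(pred_labels, true_labels) -> ConfusionCounts:
    """Count TP/FP/FN/TN with class 1 (liana wood) as positive."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValidationError(f"length mismatch: {pred.shape} vs {true.shape}")
    for arr, name in ((pred, "pred"), (true, "true")):
        if arr.size and not np.isin(arr, (LIANA, OTHER)).all():
            raise ValidationError(f"{name} labels must be in {{1, 2}}")
    pred_pos = pred == LIANA
    true_pos = true == LIANA
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & true_pos)),
        fp=int(np.sum(pred_pos & ~true_pos)),
        fn=int(np.sum(~pred_pos & true_pos)),
        tn=int(np.sum(~pred_pos & ~true_pos)),
    )


def precision_recall_f1_fpr(
    counts: ConfusionCounts,
) -> tuple[float, float, float, float, tuple[str, ...]]:
    """Precision, recall, F1 and FPR from confusion counts.

    A zero denominator yields 0 for that metric and is reported in the
    returned ``undefined`` tuple (the field data of the source study never
    hits these cases; synthetic edge cases can).
    """
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    precision = ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = ratio(counts.tp, counts.tp + counts.fn, "recall")
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        undefined.append("f1")
        f1 = 0.0
    fpr = ratio(counts.fp, counts.fp + counts.tn, "fpr")
    return precision, recall, f1, fpr, tuple(undefined)


def pr_curve_and_ap(probs, true_labels) -> tuple[list[tuple[float, float, float]], float]:
    """Precision-recall curve over the distinct probabilities, plus AP.

    Thresholds are the sorted distinct predicted probabilities, descending;
    a point is predicted positive at threshold t when its probability is
    >= t. AP = sum_k (R_k - R_{k-1}) * P_k with R_0 = 0 (no interpolation).
    """
    p = np.asarray(probs, dtype=np.float64)
    true = np.asarray(true_labels)
    if p.shape != true.shape:
        raise ValidationError(f"length mismatch: {p.shape} vs {true.shape}")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    pos = true == LIANA
    n_pos = int(pos.sum())
    if n_pos == 0 or n_pos == p.size:
        raise ValidationError("PR curve needs both classes present in the truth")
    order = np.argsort(-p, kind="stable")
    p_sorted = p[order]
    pos_sorted = pos[order]
    cum_tp = np.cumsum(pos_sorted)
    cum_pp = np.arange(1, p.size + 1)
    # last occurrence of each distinct probability in the sorted order
    last = np.flatnonzero(np.diff(p_sorted, append=-np.inf) != 0)
    thresholds = p_sorted[last]
    tp = cum_tp[last]
    pp = cum_pp[last]
    precision = tp / pp
    recall = tp / n_pos
    # recall increments as integer TP differences so that a perfect
    # ranking yields AP = 1 exactly
    delta_tp = np.diff(tp, prepend=0)
    ap = float(np.sum(delta_tp * precision) / n_pos)
    curve = [
        (float(t), float(pr), float(rc))
        for t, pr, rc in zip(thresholds, precision, recall)
    ]
    return curve, ap


def evaluate_predictions(pred_labels, true_labels, probs=None) -> EvaluationReport:
    """Full report for one set of predictions.

    The PR curve and AP are included when probabilities are given and the
    truth contains both classes; a single-class truth (possible in small
    spatial folds) yields a report with ``ap=None`` and an ``ap`` flag in
    ``undefined`` instead of an error.
    """
    counts = confusion(pred_labels, true_labels)
    precision, recall, f1, fpr, undefined = precision_recall_f1_fpr(counts)
    ap = None
    curve = None
    if probs is not None:
        true = np.asarray(true_labels)
        if 0 < np.sum(true == LIANA) < true.size:
            curve, ap = pr_curve_and_ap(probs, true_labels)
        else:
            undefined = undefined + ("ap",)
    return EvaluationReport(
        counts=counts, precision=precision, recall=recall, f1=f1, fpr=fpr,
        ap=ap, pr_curve=curve, undefined=undefined,
    )


def aggregate_reports(reports: list[EvaluationReport]) -> dict:
    """Arithmetic mean and standard deviation of per-fold metrics.

    Cross-validation results are summarized as mean +/- sd of each metric
    across folds; note the mean F1 is therefore not the harmonic mean of
    the mean precision and mean recall.
    """
    if not reports:
        raise ValidationError("no reports to aggregate")
    out: dict = {"n_folds": len(reports), "per_fold": [r.to_dict() for r in reports]}
    for name in ("precision", "recall", "f1", "fpr", "ap"):
        values = [getattr(r, name) for r in reports]
        if any(v is None for v in values):
            continue
        arr = np.asarray(values, dtype=np.float64)
        out[f"{name}_mean"] = float(arr.mean())
        out[f"{name}_sd"] = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return out


def plot_pr_curve(report: EvaluationReport, ax=None, label: str | None = None):
    """Plot the PR curve of a report (requires matplotlib)."""
    if report.pr_curve is None:
        raise ValidationError("report has no PR curve (no probabilities given)")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    recalls = [rc for _, _, rc in report.pr_curve]
    precisions = [pr for _, pr, _ in report.pr_curve]
    text = f"AP = {report.ap:.2f}" if report.ap is not None else None
    ax.plot(recalls, precisions, drawstyle="steps-post",
            label=label or text)
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower left")
    return ax
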