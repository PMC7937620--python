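"""Binary-classification metrics: confusion matrices, ROC/AUC, and the
least-error threshold.

The ROC is built by a threshold sweep over the unique scores and the AUC by
the trapezoidal rule, which makes it equal to the rank statistic (probability
that a random positive outscores a random negative, ties counted half).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "EvaluationReport",
    "confusion_at",
    "roc_auc",
    "best_threshold",
    "f_measure",
    "evaluate",
]


@dataclass
class EvaluationReport:
    tp: int
    tn: int
    fp: int
    fn: int
    threshold: float
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    undefined: list[str]
    roc: list[tuple[float, float]] | None = None
    auc: float | None = None
    best_threshold: float | None = None
    best_error: float | None = None

    def write(self, out_dir: str | os.PathLike) -> None:
        os.makedirs(out_dir, exist_ok=True)
        payload = asdict(self)
        payload.pop("roc")
        with open(os.path.join(out_dir, "report.json"), "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
        with open(os.path.join(out_dir, "confusion.tsv"), "wt", encoding="utf-8") as fh:
            fh.write("\tpred_pos\tpred_neg\n")
            fh.write(f"true_pos\t{self.tp}\t{self.fn}\n")
            fh.write(f"true_neg\t{self.fp}\t{self.tn}\n")
        if self.roc is not None:
            with open(os.path.join(out_dir, "roc.tsv"), "wt", encoding="utf-8") as fh:
                fh.write("fpr\ttpr\n")
                for fpr, tpr in self.roc:
                    fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    return scores, labels


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def confusion_at(scores, labels, threshold: float) -> EvaluationReport:
    """Confusion counts and derived metrics at ``prediction = score >= threshold``.

    Undefined ratios (0/0) are reported as 0 and listed in ``undefined``.
    """
    scores, labels = _check(scores, labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    return EvaluationReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        threshold=float(threshold),
        accuracy=(tp + tn) / len(labels),
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f_measure(precision, recall),
        undefined=undefined,
    )


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points from a sweep over unique scores and the trapezoidal AUC."""
    scores, labels = _check(scores, labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(np.sum(y_sorted[i:j] == 1))
        fp += int(np.sum(y_sorted[i:j] == 0))
        points.append((fp / n_neg, tp / n_pos))
        i = j
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def best_threshold(scores, labels) -> tuple[float, float]:
    """Threshold with the least misclassification error.

    Candidates are the midpoints of consecutive unique scores plus one
    candidate below the minimum and one above the maximum; ties resolve to
    the smallest candidate. Returns ``(threshold, error_rate)``.
    """
    scores, labels = _check(scores, labels)
    u = np.unique(scores)
    candidates = [u[0] / 2.0 if u[0] > 0 else u[0] - 0.5]
    candidates += [(a + b) / 2.0 for a, b in zip(u[:-1], u[1:])]
    candidates.append((u[-1] + 1.0) / 2.0 if u[-1] < 1 else u[-1] + 0.5)
    best_t, best_err = None, np.inf
    for t in candidates:
        err = int(np.sum((scores >= t) != (labels == 1)))
        if err < best_err:
            best_t, best_err = t, err
    return float(best_t), best_err / len(labels)


def evaluate(scores, labels, threshold: float | None = None) -> EvaluationReport:
    """Full report: confusion at the given (or least-error) threshold plus ROC/AUC."""
    scores, labels = _check(scores, labels)
    best_t, best_err = best_threshold(scores, labels)
    if threshold is None:
        threshold = best_t
    report = confusion_at(scores, labels, threshold)
    report.roc, report.auc = roc_auc(scores, labels)
    report.best_threshold = best_t
    report.best_error = best_err
    return report
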