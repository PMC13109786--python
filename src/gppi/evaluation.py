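"""Classification metrics and threshold analysis for pair scores.

Conventions (they matter at the boundaries):

* a pair is predicted positive iff its score is **>=** the threshold;
* MCC uses the four-cell formula with the standard zero-denominator
  convention (any zero factor -> MCC = 0);
* AUC is the trapezoidal integral of the ROC curve, which equals the
  Mann-Whitney probability that a random positive outscores a random
  negative (ties counted 1/2);
* precision at a threshold where nothing is predicted positive is reported
  as 1.0 together with an explicit ``undefined`` flag, so threshold scans
  are not poisoned by 0/0;
* the optimal threshold maximizes precision among all candidate thresholds
  whose sensitivity stays at or above a floor (default 0.96), ties broken
  by the largest threshold.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import roc_curve

from .errors import MetricError

DEFAULT_MIN_SENSITIVITY = 0.96


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise MetricError(
            f"scores and labels must be equal-length 1-d arrays "
            f"(got {scores.shape} vs {labels.shape})")
    if scores.size == 0:
        raise MetricError("no scored pairs")
    if np.any((scores < 0) | (scores > 1)):
        raise MetricError("scores must lie in [0, 1]")
    if not set(np.unique(labels)) <= {0, 1}:
        raise MetricError("labels must be binary")
    return scores, labels


def confusion_at(scores, labels, threshold: float) -> ConfusionCounts:
    """Confusion counts under the >= prediction rule."""
    scores, labels = _validate(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]."""
    if c.total == 0:
        raise MetricError("MCC undefined for zero pairs")
    tp, fp, tn, fn = (float(c.tp), float(c.fp), float(c.tn), float(c.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (trapezoidal integral)."""
    scores, labels = _validate(scores, labels)
    if labels.min() == labels.max():
        raise MetricError("AUC undefined: only one class present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


@dataclass
class ThresholdCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    sensitivity: np.ndarray
    precision_undefined: np.ndarray  # bool: no positive predictions there

    def to_text(self) -> str:
        lines = ["threshold\tprecision\tsensitivity\tprecision_undefined"]
        for t, p, s, u in zip(self.thresholds, self.precision,
                              self.sensitivity, self.precision_undefined):
            lines.append(f"{float(t)!r}\t{float(p)!r}\t{float(s)!r}\t{int(u)}")
        return "\n".join(lines) + "\n"


def _precision_sensitivity(c: ConfusionCounts):
    undefined = (c.tp + c.fp) == 0
    precision = 1.0 if undefined else c.tp / (c.tp + c.fp)
    sensitivity = 0.0 if (c.tp + c.fn) == 0 else c.tp / (c.tp + c.fn)
    return precision, sensitivity, undefined


def threshold_curve(scores, labels, grid) -> ThresholdCurve:
    """Precision and sensitivity as functions of the decision threshold."""
    scores, labels = _validate(scores, labels)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise MetricError("threshold grid must be sorted ascending")
    prec, sens, undef = [], [], []
    for t in grid:
        p, s, u = _precision_sensitivity(confusion_at(scores, labels, t))
        prec.append(p)
        sens.append(s)
        undef.append(u)
    return ThresholdCurve(grid, np.array(prec), np.array(sens),
                          np.array(undef, dtype=bool))


def optimal_threshold(scores, labels,
                      min_sensitivity: float = DEFAULT_MIN_SENSITIVITY) -> float:
    """Highest-precision threshold subject to a sensitivity floor.

    Candidates are the unique score values plus 0 (threshold 0 predicts
    everything positive, so any floor <= 1 is always achievable there).
    Ties in precision are broken by the largest threshold.
    """
    scores, labels = _validate(scores, labels)
    if labels.min() == labels.max():
        raise MetricError("optimal threshold needs both classes")
    if not (0.0 < min_sensitivity <= 1.0):
        raise MetricError(
            f"sensitivity floor {min_sensitivity} not achievable at any threshold")
    candidates = np.unique(np.append(scores, 0.0))
    best_t, best_prec = None, -1.0
    for t in candidates:
        p, s, _ = _precision_sensitivity(confusion_at(scores, labels, t))
        if s >= min_sensitivity and p >= best_prec:
            # >= keeps the LARGEST threshold among precision ties
            best_t, best_prec = float(t), p
    return best_t


@dataclass
class EvaluationReport:
    """Per-class and aggregate metrics at one threshold."""

    threshold: float
    counts: ConfusionCounts
    accuracy: float
    mcc: float
    auc: float
    per_class: dict          # {"0": {...}, "1": {...}} precision/recall/f1/support
    macro_avg: dict
    weighted_avg: dict

    def to_json(self) -> str:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return json.dumps(d, indent=2)

    def to_text(self) -> str:
        rows = [f"threshold\t{self.threshold}",
                f"tp\t{self.counts.tp}", f"fp\t{self.counts.fp}",
                f"tn\t{self.counts.tn}", f"fn\t{self.counts.fn}",
                f"accuracy\t{self.accuracy:.6f}", f"mcc\t{self.mcc:.6f}",
                f"auc\t{self.auc:.6f}"]
        for cls in ("0", "1"):
            m = self.per_class[cls]
            rows.append(f"class{cls}\tprecision={m['precision']:.6f}\t"
                        f"recall={m['recall']:.6f}\tf1={m['f1']:.6f}\t"
                        f"support={m['support']}")
        for name, m in (("macro", self.macro_avg), ("weighted", self.weighted_avg)):
            rows.append(f"{name}\tprecision={m['precision']:.6f}\t"
                        f"recall={m['recall']:.6f}\tf1={m['f1']:.6f}")
        return "\n".join(rows) + "\n"


def _prf(tp, fp, fn):
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    return precision, recall, f1


def evaluation_report(scores, labels, threshold: float) -> EvaluationReport:
    """Full report: per-class precision/recall/F1, accuracy, macro and
    support-weighted averages, MCC and AUC."""
    scores, labels = _validate(scores, labels)
    c = confusion_at(scores, labels, threshold)
    # class 1 = binders; class 0 metrics treat "predicted negative" as positive
    p1, r1, f1_1 = _prf(c.tp, c.fp, c.fn)
    p0, r0, f1_0 = _prf(c.tn, c.fn, c.fp)
    n0, n1 = c.tn + c.fp, c.tp + c.fn
    per_class = {
        "0": {"precision": p0, "recall": r0, "f1": f1_0, "support": n0},
        "1": {"precision": p1, "recall": r1, "f1": f1_1, "support": n1},
    }
    macro = {k: (per_class["0"][k] + per_class["1"][k]) / 2
             for k in ("precision", "recall", "f1")}
    total = n0 + n1
    weighted = {k: (per_class["0"][k] * n0 + per_class["1"][k] * n1) / total
                for k in ("precision", "recall", "f1")}
    try:
        auc = roc_auc(scores, labels)
    except MetricError:
        auc = float("nan")
    return EvaluationReport(
        threshold=float(threshold),
        counts=c,
        accuracy=(c.tp + c.tn) / c.total,
        mcc=mcc(c),
        auc=auc,
        per_class=per_class,
        macro_avg=macro,
        weighted_avg=weighted,
    )
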