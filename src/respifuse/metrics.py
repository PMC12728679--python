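"""Binary-classification evaluation: confusion counts, the seven headline
metrics (ACC, precision, sensitivity, specificity, F1, AUC, MCC) and ROC
construction with the Youden-index operating point.

Conventions: any metric whose denominator is zero is reported as 0 (the
continuous-limit convention, applied in particular to MCC); the AUC is
always the full-curve trapezoid integral; the reported operating threshold
maximizes Youden's J = TPR - FPR, ties resolved toward the *lower*
threshold (higher sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")
        if self.total == 0:
            raise InputError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Headline metrics plus (optionally) the full ROC curve."""

    acc: float
    pers: float
    sens: float
    spec: float
    f1_s: float
    mcc: float
    auc: float = float("nan")
    threshold: float = float("nan")
    youden_index: float = float("nan")
    fpr_curve: np.ndarray | None = None
    tpr_curve: np.ndarray | None = None

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "PERS": self.pers, "SENS": self.sens,
                "SPEC": self.spec, "F1_S": self.f1_s, "AUC": self.auc,
                "MCC": self.mcc, "threshold": self.threshold,
                "youden_index": self.youden_index}


def confusion(labels, predictions) -> ConfusionCounts:
    """Exact integer confusion counts from aligned binary sequences."""
    y = np.asarray(labels, dtype=int).ravel()
    p = np.asarray(predictions, dtype=int).ravel()
    if y.size == 0:
        raise InputError("empty label sequence")
    if y.size != p.size:
        raise InputError("labels and predictions have different lengths")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise InputError("labels and predictions must be binary 0/1")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """ACC, precision, sensitivity (TPR), specificity (1-FPR), F1 and MCC
    from counts alone."""
    acc = (c.tp + c.tn) / c.total
    pers = _ratio(c.tp, c.tp + c.fp)
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    f1 = _ratio(2 * pers * sens, pers + sens)
    denom = ((c.fp + c.tp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom) if denom > 0 else 0.0
    return MetricsReport(acc=acc, pers=pers, sens=sens, spec=spec,
                         f1_s=f1, mcc=float(mcc))


def roc_curve(labels, scores) -> MetricsReport:
    """Full ROC sweep over the unique scores, trapezoid AUC and the Youden
    operating point; confusion metrics are reported at that threshold."""
    y = np.asarray(labels, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.size != s.size:
        raise InputError("labels and scores have different lengths")
    if y.size == 0:
        raise InputError("empty input")
    if not np.isfinite(s).all():
        raise InputError("scores contain non-finite values")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise InputError("AUC undefined: both classes must be present")

    thresholds = np.unique(s)  # ascending
    # predict positive where score >= threshold
    tpr = np.array([np.sum((s >= t) & (y == 1)) / n_pos for t in thresholds])
    fpr = np.array([np.sum((s >= t) & (y == 0)) / n_neg for t in thresholds])
    # curve from (0,0) [threshold above max] to (1,1) [threshold below min]
    fpr_curve = np.concatenate([[0.0], fpr[::-1], [1.0]])
    tpr_curve = np.concatenate([[0.0], tpr[::-1], [1.0]])
    auc = float(np.trapezoid(tpr_curve, fpr_curve))

    j = tpr - fpr
    best = int(np.flatnonzero(j == j.max())[0])  # ties -> lower threshold
    threshold = float(thresholds[best])

    report = compute_metrics(confusion(y, (s >= threshold).astype(int)))
    report.auc = auc
    report.threshold = threshold
    report.youden_index = float(j[best])
    report.fpr_curve = fpr_curve
    report.tpr_curve = tpr_curve
    return report


def evaluate_predictions(labels, scores, threshold: float | None = None
                         ) -> MetricsReport:
    """Metrics at a fixed threshold (default: the Youden optimum), with the
    full-curve AUC attached."""
    full = roc_curve(labels, scores)
    if threshold is None:
        return full
    s = np.asarray(scores, dtype=float).ravel()
    report = compute_metrics(confusion(labels, (s >= threshold).astype(int)))
    report.auc = full.auc
    report.threshold = float(threshold)
    report.youden_index = report.sens + report.spec - 1.0
    report.fpr_curve = full.fpr_curve
    report.tpr_curve = full.tpr_curve
    return report
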