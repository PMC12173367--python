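"""Confusion matrices and the beat-classification metric suite.

All metrics are one-vs-rest per class, expressed as percentages:

    Acc = (TP + TN) / (TP + TN + FP + FN) * 100
    Sen = TP / (TP + FN) * 100                 (recall)
    PPV = TP / (TP + FP) * 100                 (precision)
    F1  = 2 * PPV * Sen / (PPV + Sen)          (harmonic mean)

Macro scores are unweighted arithmetic means over the L classes; on
imbalanced beat data they expose minority-class behaviour that overall
accuracy hides.  Zero-denominator metrics evaluate to 0 and set a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion_matrix",
    "per_class_metrics",
    "macro_scores",
    "f1_score",
    "evaluate_predictions",
    "ablation_report",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = true class, cols = predicted
    classes: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    classes: list[str]
    acc: np.ndarray
    sen: np.ndarray
    ppv: np.ndarray
    f1: np.ndarray
    overall_acc: float
    macro_sen: float
    macro_ppv: float
    macro_f1: float
    zero_division_flags: list[str] = field(default_factory=list)

    def as_dict(self, ndigits: int = 2) -> dict:
        per_class = {
            c: {
                "acc": round(float(a), ndigits),
                "sen": round(float(s), ndigits),
                "ppv": round(float(p), ndigits),
                "f1": round(float(f), ndigits),
            }
            for c, a, s, p, f in zip(self.classes, self.acc, self.sen, self.ppv, self.f1)
        }
        return {
            "per_class": per_class,
            "overall_acc": round(self.overall_acc, ndigits),
            "macro_sen": round(self.macro_sen, ndigits),
            "macro_ppv": round(self.macro_ppv, ndigits),
            "macro_f1": round(self.macro_f1, ndigits),
        }


def confusion_matrix(y_true, y_pred, classes) -> ConfusionMatrix:
    """counts[i, j] = number of samples of true class i predicted as class j."""
    classes = list(classes)
    lut = {c: i for i, c in enumerate(classes)}
    try:
        t = [lut[c] for c in y_true]
        p = [lut[c] for c in y_pred]
    except KeyError as e:
        raise ValueError(f"label {e.args[0]!r} not in class list {classes}") from None
    if len(t) != len(p):
        raise ValueError("y_true and y_pred must have equal length")
    if not t:
        counts = np.zeros((len(classes), len(classes)), dtype=int)
    else:
        counts = _sk_confusion(t, p, labels=range(len(classes)))
    return ConfusionMatrix(counts=counts, classes=classes)


def f1_score(sen: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and PPV (inputs and output as percentages)."""
    if sen + ppv == 0:
        return 0.0
    return 2.0 * ppv * sen / (ppv + sen)


def per_class_metrics(cm: ConfusionMatrix) -> EvalReport:
    """One-vs-rest Acc/Sen/PPV/F1 per class plus overall and macro scores."""
    counts = np.asarray(cm.counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    total = counts.sum()
    tp = np.diag(counts)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    tn = total - tp - fn - fp

    flags: list[str] = []

    def _safe(num, den, name):
        out = np.zeros_like(num)
        for i, (n_, d_) in enumerate(zip(num, den)):
            if d_ == 0:
                flags.append(f"{name}[{cm.classes[i]}]: zero denominator")
            else:
                out[i] = n_ / d_ * 100.0
        return out

    acc = (tp + tn) / total * 100.0
    sen = _safe(tp, tp + fn, "sen")
    ppv = _safe(tp, tp + fp, "ppv")
    f1 = np.array([f1_score(s, p) for s, p in zip(sen, ppv)])

    report = EvalReport(
        classes=list(cm.classes),
        acc=acc,
        sen=sen,
        ppv=ppv,
        f1=f1,
        overall_acc=float(tp.sum() / total * 100.0),
        macro_sen=float(sen.mean()),
        macro_ppv=float(ppv.mean()),
        macro_f1=float(f1.mean()),
        zero_division_flags=flags,
    )
    return report


def macro_scores(report: EvalReport) -> tuple[float, float, float]:
    """(macro sensitivity, macro PPV, macro F1) as unweighted means."""
    return (
        float(np.mean(report.sen)),
        float(np.mean(report.ppv)),
        float(np.mean(report.f1)),
    )


def evaluate_predictions(y_true, y_pred, classes) -> EvalReport:
    return per_class_metrics(confusion_matrix(y_true, y_pred, classes))


def ablation_report(variant_reports: dict[str, EvalReport]) -> list[dict]:
    """One row per model variant: overall Acc, macro Sen, macro PPV, Macro-F1.

    All variants must have been evaluated on the same class list (same
    split); mismatched class lists raise.
    """
    if len(variant_reports) < 2:
        raise ValueError("an ablation needs at least two variants")
    ref_classes = None
    rows = []
    for name, rep in variant_reports.items():
        if ref_classes is None:
            ref_classes = rep.classes
        elif rep.classes != ref_classes:
            raise ValueError("ablation variants were evaluated on different class lists")
        rows.append(
            {
                "variant": name,
                "overall_acc": round(rep.overall_acc, 2),
                "macro_sen": round(rep.macro_sen, 2),
                "macro_ppv": round(rep.macro_ppv, 2),
                "macro_f1": round(rep.macro_f1, 2),
            }
        )
    return rows
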