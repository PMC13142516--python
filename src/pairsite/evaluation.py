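"""Residue-level evaluation: confusion counts, imbalance-robust metrics,
threshold-free curves, confusion reconstruction from printed summaries, and
the scrambled-partner control.

Interface prediction is a heavily imbalanced problem (typically 1.7–3.5%
positive residues), so accuracy alone is uninformative; MCC and the
precision–recall curve carry most of the signal.  Metrics are micro-averaged:
residues are pooled across all pairs before counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "metrics_from_confusion",
    "reconstruct_confusion",
    "auroc",
    "prauc",
    "scramble_partner",
    "evaluate_tracks",
]

DEFAULT_CUTOFF = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @property
    def positives(self) -> int:
        return self.TP + self.FN


@dataclass
class MetricReport:
    """Threshold metrics in percent (accuracy/recall/precision) and unitless
    F1/MCC; AUROC/PRAUC filled only when score vectors are available."""

    accuracy: float
    recall: float
    precision: float
    f1: float
    mcc: float
    support_positive: int
    support_total: int
    auroc: float | None = None
    prauc: float | None = None
    degenerate: set = field(default_factory=set)


def confusion(
    probabilities: np.ndarray, labels: np.ndarray, cutoff: float = DEFAULT_CUTOFF
) -> ConfusionCounts:
    """Tally the 2x2 table; a probability equal to the cutoff counts positive."""
    p = np.asarray(probabilities, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    if p.size != y.size:
        raise ValueError(f"length mismatch: {p.size} vs {y.size}")
    calls = p >= cutoff
    return ConfusionCounts(
        TP=int(np.sum(calls & y)),
        FP=int(np.sum(calls & ~y)),
        FN=int(np.sum(~calls & y)),
        TN=int(np.sum(~calls & ~y)),
        cutoff=cutoff,
    )


def metrics_from_confusion(c: ConfusionCounts) -> MetricReport:
    """Standard formulas; any zero denominator yields 0 plus a degeneracy flag
    so batch reports never crash on an all-negative predictor."""
    degenerate: set = set()

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.add(name)
            return 0.0
        return num / den

    recall = ratio(c.TP, c.TP + c.FN, "recall")
    precision = ratio(c.TP, c.TP + c.FP, "precision")
    accuracy = (c.TP + c.TN) / c.total
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    mcc_den = np.sqrt(
        float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = ratio(c.TP * c.TN - c.FP * c.FN, mcc_den, "mcc")
    return MetricReport(
        accuracy=100.0 * accuracy,
        recall=100.0 * recall,
        precision=100.0 * precision,
        f1=f1,
        mcc=mcc,
        support_positive=c.positives,
        support_total=c.total,
        degenerate=degenerate,
    )


def reconstruct_confusion(
    recall_pct: float, precision_pct: float, positives: int, total: int
) -> ConfusionCounts:
    """Invert printed recall/precision plus dataset totals back to counts.

    TP is rounded first, then FP from the precision ratio; lets published
    summary rows be checked for internal consistency (accuracy, MCC, F1).
    """
    if not (0 < recall_pct <= 100 and 0 < precision_pct <= 100):
        raise ValueError("recall and precision must lie in (0, 100]")
    if positives > total:
        raise ValueError("positives must not exceed total")
    TP = round(recall_pct / 100.0 * positives)
    FP = round(TP * (100.0 / precision_pct - 1.0))
    FN = positives - TP
    TN = total - TP - FP - FN
    if min(TP, FP, FN, TN) < 0:
        raise ValueError("inconsistent summary statistics: negative reconstructed count")
    return ConfusionCounts(TP=TP, FP=FP, FN=FN, TN=TN)


def _check_both_classes(y: np.ndarray) -> None:
    if y.all() or not y.any():
        raise ValueError("AUROC/PRAUC undefined: labels contain a single class")


def auroc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUROC (ties count one half)."""
    y = np.asarray(labels).ravel().astype(bool)
    _check_both_classes(y)
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=np.float64).ravel()))


def prauc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision–recall curve via stepwise interpolation
    over recall (average precision)."""
    y = np.asarray(labels).ravel().astype(bool)
    _check_both_classes(y)
    return float(
        average_precision_score(y, np.asarray(probabilities, dtype=np.float64).ravel())
    )


def scramble_partner(sequence: str, seed: int) -> str:
    """Uniform seeded permutation of a sequence: residue composition is
    preserved while every positional motif is destroyed — the control that
    quantifies how much a prediction depends on partner identity."""
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    rng = np.random.default_rng(seed)
    chars = np.array(list(sequence))
    return "".join(chars[rng.permutation(len(chars))])


def evaluate_tracks(
    probabilities: list[np.ndarray],
    labels: list[np.ndarray],
    cutoff: float = DEFAULT_CUTOFF,
) -> MetricReport:
    """Micro-averaged report over many pairs: residues pooled, then scored."""
    p = np.concatenate([np.asarray(x).ravel() for x in probabilities])
    y = np.concatenate([np.asarray(x).ravel() for x in labels])
    report = metrics_from_confusion(confusion(p, y, cutoff))
    if 0 < y.sum() < y.size:
        report.auroc = auroc(p, y)
        report.prauc = prauc(p, y)
    return report
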