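"""Shared-task style scoring for DDI classification.

Per-class and micro-averaged precision/recall/F1 over the four positive DDI
classes (advice, effect, int, mechanism).  The non-interaction class ``other``
is never a row of its own: it contributes only as a source or sink of errors.
A positive-to-positive confusion counts twice — as a false negative of the
gold class and a false positive of the predicted class — which is exactly the
convention under which per-class counts sum to the overall row.

Model comparison uses a 1-df chi-square over the 2x2 table
(model x correct/incorrect), without continuity correction; two models differ
significantly iff chi2 > 3.84 and p < 0.05.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .corpus import ClassLabel, POSITIVE_LABELS
from .preprocess import BlindedInstance

CHI2_THRESHOLD = 3.84
P_THRESHOLD = 0.05


@dataclass
class ConfusionCounts:
    """Per-positive-class TP/FP/FN plus the gold total of each class."""

    tp: dict[ClassLabel, int] = field(default_factory=dict)
    fp: dict[ClassLabel, int] = field(default_factory=dict)
    fn: dict[ClassLabel, int] = field(default_factory=dict)

    def __post_init__(self):
        for c in POSITIVE_LABELS:
            self.tp.setdefault(c, 0)
            self.fp.setdefault(c, 0)
            self.fn.setdefault(c, 0)

    def total(self, c: ClassLabel) -> int:
        return self.tp[c] + self.fn[c]

    def summed(self) -> tuple[int, int, int]:
        return (
            sum(self.tp.values()),
            sum(self.fp.values()),
            sum(self.fn.values()),
        )


def count_confusions(
    gold: Sequence[ClassLabel], pred: Sequence[ClassLabel]
) -> ConfusionCounts:
    """Confusion counts over aligned gold/predicted label sequences."""
    if len(gold) != len(pred):
        raise ValueError(f"gold has {len(gold)} labels, pred has {len(pred)}")
    counts = ConfusionCounts()
    for g, p in zip(gold, pred):
        if g == p:
            if g is not ClassLabel.OTHER:
                counts.tp[g] += 1
            continue
        if g is not ClassLabel.OTHER:
            counts.fn[g] += 1
        if p is not ClassLabel.OTHER:
            counts.fp[p] += 1
    return counts


def _round2(x: float) -> float:
    # half-even, the convention the printed tables follow
    return round(x, 2)


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(P, R, F1) as percentages rounded to two decimals.

    Conventions: P = 0 when tp+fp = 0, R = 0 when tp+fn = 0, F1 = 0 when
    P + R = 0.  F1 is computed from the unrounded P and R.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return _round2(100 * p), _round2(100 * r), _round2(100 * f1)


def micro_overall(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Micro-averaged (P, R, F1): counts summed over the four positive classes."""
    return precision_recall_f1(*counts.summed())


@dataclass
class MetricsReport:
    """Per-class rows, the overall row, and optional per-provenance reports."""

    counts: ConfusionCounts
    per_class: dict[ClassLabel, tuple[float, float, float]]
    overall: tuple[float, float, float]
    subreports: dict[str, "MetricsReport"] = field(default_factory=dict)

    @classmethod
    def from_labels(cls, gold, pred) -> "MetricsReport":
        counts = count_confusions(gold, pred)
        per_class = {
            c: precision_recall_f1(counts.tp[c], counts.fp[c], counts.fn[c])
            for c in POSITIVE_LABELS
        }
        return cls(counts=counts, per_class=per_class, overall=micro_overall(counts))

    def to_rows(self) -> list[tuple]:
        rows = []
        for c in POSITIVE_LABELS:
            p, r, f1 = self.per_class[c]
            rows.append((c.value, self.counts.tp[c], self.counts.fp[c],
                         self.counts.fn[c], self.counts.total(c), p, r, f1))
        tp, fp, fn = self.counts.summed()
        p, r, f1 = self.overall
        rows.append(("overall", tp, fp, fn, tp + fn, p, r, f1))
        return rows


def per_corpus_report(
    instances: Sequence[BlindedInstance],
    gold: Sequence[ClassLabel],
    pred: Sequence[ClassLabel],
) -> MetricsReport:
    """Global report plus one sub-report per provenance of the instances."""
    if not (len(instances) == len(gold) == len(pred)):
        raise ValueError("instances, gold and pred must be aligned")
    report = MetricsReport.from_labels(gold, pred)
    by_prov: dict[str, list[int]] = {}
    for i, inst in enumerate(instances):
        by_prov.setdefault(inst.provenance, []).append(i)
    for prov, idx in sorted(by_prov.items()):
        report.subreports[prov] = MetricsReport.from_labels(
            [gold[i] for i in idx], [pred[i] for i in idx]
        )
    return report


def chi_square_compare(
    gold_a: Sequence[ClassLabel],
    pred_a: Sequence[ClassLabel],
    gold_b: Sequence[ClassLabel],
    pred_b: Sequence[ClassLabel],
) -> tuple[float, float, bool]:
    """Compare two models scored against the same gold labels.

    Builds the 2x2 contingency table model x (correct, incorrect) over all
    candidate instances and computes the 1-df chi-square statistic without
    continuity correction.  Significant iff chi2 > 3.84 (strict) and p < 0.05.
    """
    if list(gold_a) != list(gold_b):
        raise ValueError("the two prediction sets must share one gold standard")
    table = np.array(
        [
            _correct_incorrect(gold_a, pred_a),
            _correct_incorrect(gold_b, pred_b),
        ],
        dtype=float,
    )
    if table[0].tolist() == table[1].tolist():
        return 0.0, 1.0, False
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / table.sum()
    if np.any(expected == 0):
        return 0.0, 1.0, False
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p, bool(chi2 > CHI2_THRESHOLD and p < P_THRESHOLD)


def _correct_incorrect(gold, pred) -> tuple[int, int]:
    correct = sum(1 for g, p in zip(gold, pred) if g == p)
    return correct, len(gold) - correct


def entity_distance_stats(
    instances: Iterable[BlindedInstance],
) -> tuple[Counter, float]:
    """Histogram of token distances p2 - p1 between the paired entities,
    and their mean — the corpus statistic that motivates the filter widths."""
    hist: Counter = Counter()
    total = 0
    count = 0
    for inst in instances:
        d = inst.entity_distance
        hist[d] += 1
        total += d
        count += 1
    mean = total / count if count else 0.0
    return hist, mean
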