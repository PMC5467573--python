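"""Study protocol: validation split, sweeps, and learning curves.

The validation split is drawn at the sentence level — all instances of one
sentence land on the same side — because candidate pairs from one sentence are
nearly identical token sequences and would leak across an instance-level
split.  Sweeps train one model per named configuration on a shared split,
rank configurations by validation micro-F1, and compare every pair of
configurations with the chi-square protocol of :mod:`ddicnn.evaluation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .cnn import CNNDDIClassifier
from .corpus import ClassLabel
from .evaluation import MetricsReport, chi_square_compare
from .preprocess import BlindedInstance


@dataclass(frozen=True)
class SplitSpec:
    validation_fraction: float = 0.10
    seed: int = 0
    tolerance: float = 0.02  # realized fraction may deviate this much


def split_train_validation(
    instances: Sequence[BlindedInstance], spec: SplitSpec = SplitSpec()
) -> tuple[list[BlindedInstance], list[BlindedInstance]]:
    """Partition instances by sentence id, targeting the validation fraction.

    Sentences are shuffled under the spec's seed and accumulated into the
    validation side until its instance share reaches the target; no sentence
    ever straddles the split.
    """
    by_sentence: dict[str, list[BlindedInstance]] = {}
    for inst in instances:
        by_sentence.setdefault(inst.sentence_id, []).append(inst)
    if len(by_sentence) < 2:
        raise ValueError("need at least 2 sentences to split")
    rng = np.random.default_rng(spec.seed)
    sentence_ids = sorted(by_sentence)
    rng.shuffle(sentence_ids)
    target = spec.validation_fraction * len(instances)
    val_ids: set[str] = set()
    n_val = 0
    for sid in sentence_ids:
        if n_val >= target:
            break
        # take the sentence only if it brings us closer to the target
        size = len(by_sentence[sid])
        if abs(n_val + size - target) <= abs(n_val - target) or n_val == 0:
            val_ids.add(sid)
            n_val += size
    train = [i for i in instances if i.sentence_id not in val_ids]
    val = [i for i in instances if i.sentence_id in val_ids]
    return train, val


@dataclass
class RunRecord:
    """Everything needed to reproduce and inspect one sweep run."""

    name: str
    config: dict[str, Any]
    seed: int
    curve: list[dict]
    validation_report: MetricsReport
    test_report: MetricsReport | None
    val_predictions: list[ClassLabel]
    error: str | None = None

    @property
    def validation_f1(self) -> float:
        return self.validation_report.overall[2]


@dataclass
class SweepResult:
    records: list[RunRecord]
    significance: dict[tuple[str, str], tuple[float, float, bool]]
    ranking: list[str] = field(default_factory=list)

    def rank(self) -> list[str]:
        ok = [r for r in self.records if r.error is None]
        return [r.name for r in sorted(ok, key=lambda r: -r.validation_f1)]


def run_sweep(
    grid: Sequence[tuple[str, dict[str, Any]]],
    train: Sequence[BlindedInstance],
    validation: Sequence[BlindedInstance],
    test: Sequence[BlindedInstance] | None = None,
    base_config: dict[str, Any] | None = None,
) -> SweepResult:
    """Train one model per named configuration; all runs share the split.

    Each grid entry is ``(name, param_overrides)`` applied on top of
    ``base_config``.  A failed run is recorded with its error message and
    excluded from the ranking and the pairwise significance matrix.
    """
    names = [name for name, _ in grid]
    if len(set(names)) != len(names):
        raise ValueError("sweep configuration names must be unique")
    if not grid:
        raise ValueError("sweep grid is empty")
    gold_val = [inst.label for inst in validation]
    records: list[RunRecord] = []
    for name, overrides in grid:
        config = dict(base_config or {})
        config.update(overrides)
        try:
            est = CNNDDIClassifier(**config)
            est.fit(train, validation=validation)
            val_pred = est.predict(validation)
            val_report = MetricsReport.from_labels(gold_val, val_pred)
            test_report = None
            if test is not None:
                test_report = MetricsReport.from_labels(
                    [i.label for i in test], est.predict(test)
                )
            records.append(
                RunRecord(
                    name=name,
                    config=config,
                    seed=config.get("seed", 0),
                    curve=list(est.history_),
                    validation_report=val_report,
                    test_report=test_report,
                    val_predictions=val_pred,
                )
            )
        except Exception as exc:  # a failed run must not kill the sweep
            records.append(
                RunRecord(
                    name=name,
                    config=config,
                    seed=config.get("seed", 0),
                    curve=[],
                    validation_report=MetricsReport.from_labels([], []),
                    test_report=None,
                    val_predictions=[],
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    significance: dict[tuple[str, str], tuple[float, float, bool]] = {}
    ok = [r for r in records if r.error is None]
    for i, ra in enumerate(ok):
        for rb in ok[i + 1 :]:
            significance[(ra.name, rb.name)] = chi_square_compare(
                gold_val, ra.val_predictions, gold_val, rb.val_predictions
            )
    result = SweepResult(records=records, significance=significance)
    result.ranking = result.rank()
    return result


def learning_curve(record: RunRecord) -> list[dict]:
    """Per-epoch curve of a run, with the best-validation epoch flagged."""
    curve = [dict(row) for row in record.curve]
    if curve and all("val_f1" in row for row in curve):
        best = max(range(len(curve)), key=lambda i: curve[i]["val_f1"])
        for i, row in enumerate(curve):
            row["best"] = i == best
    return curve
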