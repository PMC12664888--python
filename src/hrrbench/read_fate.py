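"""Read-fate classification and binary-performance metrics.

The benchmark's positive class is *a read removed by the method*; a read's
truth status is positive when it was incorporated into the mixture from a
human-sample pool (provenance class HOST or CONTAMINANT) and negative when it
came from a target pool. Crossing fate with truth yields the per-cell
confusion matrix, from which accuracy, F1, MCC, precision, sensitivity and
specificity are computed at *read* level.

Singleton-removed reads count as removed by default (only intact non-host
pairs are retained downstream, so the orphaned mate is gone from the output);
this means a target-class mate of a flagged read becomes a false positive.
The choice is configurable via ``count_singletons_as_removed``.

Metrics with a zero denominator are reported as 0.0 with an explicit
degenerate flag rather than NaN, keeping aggregation robust while preserving
honesty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from hrrbench.removers import RemovalResult
from hrrbench.sequence_io import ProvenanceLabel, ReadPair, SourceClass

__all__ = [
    "FateTable",
    "MetricSet",
    "FnReadSet",
    "classify_fates",
    "compute_metrics",
    "expected_fate_table",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "f1", "mcc", "precision", "sensitivity", "specificity")

#: truth-positive provenance classes: reads originating from a human sample
TRUTH_POSITIVE_CLASSES = frozenset({SourceClass.HOST, SourceClass.CONTAMINANT})


@dataclass
class FateTable:
    """Read-level confusion matrix under "positive = removed"."""

    tp: float = 0
    fp: float = 0
    tn: float = 0
    fn: float = 0
    cell: Optional[Dict[str, object]] = None

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "FateTable") -> "FateTable":
        return FateTable(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricSet:
    """The six benchmark metrics; ``degenerate`` names any metric whose
    denominator was zero (value reported as 0.0)."""

    accuracy: float
    f1: float
    mcc: float
    precision: float
    sensitivity: float
    specificity: float
    degenerate: FrozenSet[str] = frozenset()

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class FnReadSet:
    """All false-negative reads of a cell: human-sample reads left retained."""

    cell: Optional[Dict[str, object]]
    reads: List[Tuple[str, int, ProvenanceLabel]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def class_census(self) -> Dict[SourceClass, int]:
        census: Dict[SourceClass, int] = {}
        for _, _, label in self.reads:
            census[label.source_class] = census.get(label.source_class, 0) + 1
        return census

    def donor_census(self) -> Dict[str, int]:
        census: Dict[str, int] = {}
        for _, _, label in self.reads:
            census[label.donor_id] = census.get(label.donor_id, 0) + 1
        return census


def classify_fates(
    result: RemovalResult,
    pairs: Sequence[ReadPair],
    count_singletons_as_removed: bool = True,
    cell: Optional[Dict[str, object]] = None,
) -> Tuple[FateTable, FnReadSet]:
    """Cross every read's fate with its provenance truth.

    ``pairs`` is the labelled input the remover saw; ``result`` keys reads by
    the encoded pair name. Raises if a read is unknown to the result or
    unlabelled.
    """
    table = FateTable(cell=cell)
    fn_set = FnReadSet(cell=cell)
    for pair in pairs:
        qname = pair.qname
        for read in (pair.r1, pair.r2):
            if read.label is None:
                raise ValueError(f"read {read.name!r} has no provenance label")
            fate = result.fate_of(qname, read.mate)
            removed = fate == "flagged" or (
                count_singletons_as_removed and fate == "singleton"
            )
            truth_pos = read.label.source_class in TRUTH_POSITIVE_CLASSES
            if truth_pos and removed:
                table.tp += 1
            elif truth_pos:
                table.fn += 1
                fn_set.reads.append((qname, read.mate, read.label))
            elif removed:
                table.fp += 1
            else:
                table.tn += 1
    return table, fn_set


def _safe_div(num: float, den: float) -> Tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def compute_metrics(t: FateTable) -> MetricSet:
    """Closed-form metrics from a confusion matrix (degenerate terms → 0, flagged)."""
    if t.total <= 0:
        raise ValueError("empty fate table")
    degenerate = set()
    accuracy = (t.tp + t.tn) / t.total
    precision, d = _safe_div(t.tp, t.tp + t.fp)
    if d:
        degenerate.add("precision")
    sensitivity, d = _safe_div(t.tp, t.tp + t.fn)
    if d:
        degenerate.add("sensitivity")
    specificity, d = _safe_div(t.tn, t.tn + t.fp)
    if d:
        degenerate.add("specificity")
    f1, d = _safe_div(2 * t.tp, 2 * t.tp + t.fp + t.fn)
    if d:
        degenerate.add("f1")
    denom2 = (t.tp + t.fp) * (t.tp + t.fn) * (t.tn + t.fp) * (t.tn + t.fn)
    if denom2 == 0:
        mcc = 0.0
        degenerate.add("mcc")
    else:
        mcc = (t.tp * t.tn - t.fp * t.fn) / math.sqrt(denom2)
    return MetricSet(
        accuracy=accuracy,
        f1=f1,
        mcc=mcc,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        degenerate=frozenset(degenerate),
    )


def expected_fate_table(
    n_host: float, n_other: float, sens: float, fpr: float
) -> FateTable:
    """Analytic expectation of the fate table under independent Bernoulli
    removal at per-read rates (sens for truth-positive reads, fpr otherwise).

    Useful for trend analysis: with fixed sens < 1 − fpr, accuracy and MCC
    decrease as the host fraction rises while F1 does not — the pattern seen
    across a titration series.
    """
    for name, v in (("sens", sens), ("fpr", fpr)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return FateTable(
        tp=sens * n_host,
        fn=(1 - sens) * n_host,
        fp=fpr * n_other,
        tn=(1 - fpr) * n_other,
    )
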