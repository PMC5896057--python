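"""Confusion statistics over concluded concepts.

Only concepts with a *univocal* expectation — exactly ``{{t}}`` or
``{{f}}`` — enter the evaluation; for those, the conclusion state maps
onto a confusion class:

* TP: Confirmed Presence
* TN: Confirmed Absence, Absent
* FP: Unexpected Presence, Contradictory Presence
* FN: Missing, Unexpected Absence, Contradictory Absence

Accuracy, precision, recall and F1 are carried as exact rationals;
percentages render half-up to two decimals.  A metric whose denominator is
zero is *undefined* (``None``), which is distinct from 0.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

from .reasoner import ReasoningState
from .truth_values import FALSE_ONLY, TRUE_ONLY, ConclusionState

_TP_STATES = {ConclusionState.CONFIRMED_PRESENCE}
_TN_STATES = {ConclusionState.CONFIRMED_ABSENCE, ConclusionState.ABSENT}
_FP_STATES = {ConclusionState.UNEXPECTED_PRESENCE,
              ConclusionState.CONTRADICTORY_PRESENCE}
_FN_STATES = {ConclusionState.MISSING, ConclusionState.UNEXPECTED_ABSENCE,
              ConclusionState.CONTRADICTORY_ABSENCE}

STATS_COLUMNS = ("Category", "TP", "TN", "FP", "FN",
                 "Accuracy", "Precision", "Recall", "F1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class Metrics:
    """Exact-rational evaluation metrics; ``None`` means undefined (0/0)."""

    accuracy: Optional[Fraction]
    precision: Optional[Fraction]
    recall: Optional[Fraction]
    f1: Optional[Fraction]


def classify(state: ReasoningState,
             categories: Optional[Iterable[str]] = None) -> ConfusionCounts:
    """Count TP/TN/FP/FN over concepts with univocal expectations.

    ``categories`` restricts counting to concepts whose category tag is in
    the given set (all categories when absent).  A univocal expectation
    forces the conclusion into one of the eight classified states; anything
    else would indicate an engine defect and raises.
    """
    wanted = set(categories) if categories is not None else None
    tp = tn = fp = fn = 0
    for nid in state.graph.identifiers():
        if state.expectations[nid] not in (TRUE_ONLY, FALSE_ONLY):
            continue
        if wanted is not None and state.graph.concept(nid).category not in wanted:
            continue
        conclusion = state.conclusions[nid]
        if conclusion in _TP_STATES:
            tp += 1
        elif conclusion in _TN_STATES:
            tn += 1
        elif conclusion in _FP_STATES:
            fp += 1
        elif conclusion in _FN_STATES:
            fn += 1
        else:  # unreachable by construction of the conclusion table
            raise AssertionError(
                "univocal expectation on %r produced unclassifiable "
                "conclusion %s" % (nid, conclusion.value))
    return ConfusionCounts(tp, tn, fp, fn)


def metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall and F1 from confusion counts.

    accuracy = (TP+TN)/(TP+FP+FN+TN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); F1 = 2PR/(P+R) = 2TP/(2TP+FP+FN).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn

    def ratio(num: int, den: int) -> Optional[Fraction]:
        return Fraction(num, den) if den else None

    return Metrics(
        accuracy=ratio(tp + tn, tp + fp + fn + tn),
        precision=ratio(tp, tp + fp),
        recall=ratio(tp, tp + fn),
        f1=ratio(2 * tp, 2 * tp + fp + fn),
    )


def percent(value: Optional[Fraction], digits: int = 2) -> str:
    """Render a ratio as a percentage, half-up; undefined renders as NA."""
    if value is None:
        return "NA"
    quantum = Decimal(1).scaleb(-digits)
    scaled = (Decimal(value.numerator) / Decimal(value.denominator) * 100)
    return str(scaled.quantize(quantum, rounding=ROUND_HALF_UP)) + "%"


def percent_value(value: Optional[Fraction], digits: int = 2) -> Optional[float]:
    """The percentage as a float rounded half-up (e.g. 78.80), or None."""
    if value is None:
        return None
    quantum = Decimal(1).scaleb(-digits)
    scaled = (Decimal(value.numerator) / Decimal(value.denominator) * 100)
    return float(scaled.quantize(quantum, rounding=ROUND_HALF_UP))


def stats_rows(state: ReasoningState) -> List[Tuple[str, ...]]:
    """One row per category present in the graph, plus an 'all' row."""
    categories = sorted({state.graph.concept(i).category
                         for i in state.graph.identifiers()})
    rows = []
    for cat in ["all"] + categories:
        counts = classify(state, None if cat == "all" else [cat])
        m = metrics(counts)
        rows.append((cat, str(counts.tp), str(counts.tn), str(counts.fp),
                     str(counts.fn), percent(m.accuracy), percent(m.precision),
                     percent(m.recall), percent(m.f1)))
    return rows


def write_stats(state: ReasoningState,
                destination: Union[str, Path, io.TextIOBase]) -> None:
    if isinstance(destination, (str, Path)):
        with open(destination, "w", newline="", encoding="utf-8") as handle:
            write_stats(state, handle)
        return
    writer = csv.writer(destination, lineterminator="\n")
    writer.writerow(STATS_COLUMNS)
    writer.writerows(stats_rows(state))
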