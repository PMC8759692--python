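"""Benchmarking of driver-gene prediction sets against positive controls.

Predictions and controls are plain sets of Entrez gene IDs (pancancer level)
or (Entrez ID, cohort) pairs (per-cohort level).  Sensitivity is the recall
of a positive-control list; specificity needs an explicit gene universe,
since "all genes" is only meaningful relative to the genes observed in the
analysed dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

LEVELS = ("gene", "gene_cohort")


@dataclass(frozen=True)
class PredictionSet:
    """A named set of predicted (or positive-control) driver items."""

    source_name: str
    level: str  # "gene" -> entrez ids; "gene_cohort" -> (entrez, cohort)
    items: frozenset

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        object.__setattr__(self, "items", frozenset(self.items))


def _check_levels(sets: Iterable[PredictionSet]) -> str:
    levels = {s.level for s in sets}
    if len(levels) != 1:
        raise ValueError(f"mixed prediction levels: {sorted(levels)}")
    return levels.pop()


def overlap_k(sets: Sequence[PredictionSet], k: int) -> PredictionSet:
    """Items predicted by at least ``k`` of the supplied sets."""
    level = _check_levels(sets)
    votes: dict = {}
    for s in sets:
        for item in s.items:
            votes[item] = votes.get(item, 0) + 1
    kept = frozenset(item for item, v in votes.items() if v >= k)
    return PredictionSet(source_name=f"overlap_{k}", level=level, items=kept)


def sensitivity(pred: PredictionSet, positive: PredictionSet) -> float:
    """Percentage of the positive-control list recovered by the prediction."""
    _check_levels([pred, positive])
    if not positive.items:
        raise ValueError("empty positive-control set")
    return 100.0 * len(pred.items & positive.items) / len(positive.items)


def specificity(
    pred: PredictionSet, positive: PredictionSet, universe: PredictionSet
) -> float:
    """Percentage of non-control universe items left unpredicted."""
    _check_levels([pred, positive, universe])
    if not positive.items <= universe.items:
        raise ValueError("positive-control set not contained in the universe")
    if not pred.items <= universe.items:
        raise ValueError("prediction set not contained in the universe")
    negatives = universe.items - positive.items
    if not negatives:
        raise ValueError("universe equals the positive-control set")
    true_neg = negatives - pred.items
    return 100.0 * len(true_neg) / len(negatives)
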