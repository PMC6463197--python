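"""Analytical Eco-Scale greenness scoring.

The Eco-Scale rates an analytical procedure by subtracting penalty points
from 100 (the ideal green analysis).  Penalty points are assigned per
reagent (amount and hazard), per instrument (energy use), and for
occupational hazard and waste generation.  The resulting score classifies
the method as an excellent (>= 75), acceptable (>= 50) or inadequate
(< 50) green analysis.

Penalty values are supplied in the method definition; deriving them from
hazard databases is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "PenaltyCategory",
    "PenaltyItem",
    "EcoScaleLedger",
    "score_ledger",
    "classify_score",
]

#: Classification thresholds of the Eco-Scale scheme (score >= threshold).
EXCELLENT_THRESHOLD = 75
ACCEPTABLE_THRESHOLD = 50


class PenaltyCategory(str, Enum):
    REAGENT = "reagent"
    INSTRUMENT = "instrument"
    OCCUPATIONAL_HAZARD = "occupational_hazard"
    WASTE = "waste"


@dataclass(frozen=True)
class PenaltyItem:
    """One line of the penalty ledger (e.g. 'Hexane, 80 uL -> 8 points')."""

    category: PenaltyCategory
    label: str
    penalty_points: int
    amount_note: str = ""

    def __post_init__(self) -> None:
        if self.penalty_points < 0:
            raise ValueError(
                f"negative penalty for {self.label!r}: {self.penalty_points}"
            )


@dataclass
class EcoScaleLedger:
    items: list[PenaltyItem] = field(default_factory=list)

    @property
    def total_penalty(self) -> int:
        return sum(item.penalty_points for item in self.items)

    @property
    def score(self) -> int:
        return 100 - self.total_penalty

    @property
    def classification(self) -> str:
        return classify_score(self.score)

    def to_dict(self) -> dict:
        return {
            "items": [
                {
                    "category": item.category.value,
                    "label": item.label,
                    "amount_note": item.amount_note,
                    "penalty_points": item.penalty_points,
                }
                for item in self.items
            ],
            "total_penalty": self.total_penalty,
            "score": self.score,
            "classification": self.classification,
        }


def classify_score(
    score: float,
    excellent: float = EXCELLENT_THRESHOLD,
    acceptable: float = ACCEPTABLE_THRESHOLD,
) -> str:
    if score >= excellent:
        return "excellent green analysis"
    if score >= acceptable:
        return "acceptable green analysis"
    return "inadequate green analysis"


def score_ledger(items: Iterable[PenaltyItem | Sequence]) -> EcoScaleLedger:
    """Total a penalty ledger and attach the Eco-Scale score.

    ``items`` may be :class:`PenaltyItem` instances or
    ``(category, label, amount_note, penalty_points)`` tuples.

    Raises ``ValueError`` for a negative penalty.
    """
    normalized: list[PenaltyItem] = []
    for item in items:
        if not isinstance(item, PenaltyItem):
            category, label, amount_note, points = item
            item = PenaltyItem(
                category=PenaltyCategory(category),
                label=str(label),
                amount_note=str(amount_note),
                penalty_points=int(points),
            )
        normalized.append(item)
    return EcoScaleLedger(items=normalized)
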