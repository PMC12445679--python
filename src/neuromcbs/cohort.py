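"""Cohort-level aggregation of n-of-1 benefit scores.

Patients scored on the Neuro-MCBS are grouped by tumour entity and the
fraction achieving the benefit threshold (final score >= 3 by default)
is reported as a whole-number percentage.  Percentages round half *up*
(5/8 -> 63%, 1/8 -> 13%), matching standard clinical reporting rather
than banker's rounding.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel

from .esmo import ScoreResult
from .records import StudyRecord

__all__ = ["CohortSummary", "round_half_up_pct", "summarize_cohort", "tabulate_therapy_classes"]

DEFAULT_THRESHOLD = 3


class CohortSummary(BaseModel):
    entity: str
    n_total: int
    n_benefit: int
    pct_benefit: Optional[int]  # None when the cohort is empty
    threshold: int

    def render_pct(self) -> str:
        return "—" if self.pct_benefit is None else f"{self.pct_benefit}%"


def round_half_up_pct(numerator: int, denominator: int) -> Optional[int]:
    """Integer percentage with ties rounded away from zero; None for 0/0."""
    if denominator == 0:
        return None
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def summarize_cohort(
    scores: Iterable[tuple[str, ScoreResult]],
    threshold: int = DEFAULT_THRESHOLD,
) -> list[CohortSummary]:
    """One summary per entity, ordered by entity name.

    ``scores`` must contain only scored results; not-assessable patients
    are excluded (and counted) by the caller before aggregation.
    """
    totals: dict[str, int] = defaultdict(int)
    benefit: dict[str, int] = defaultdict(int)
    for entity, result in scores:
        if not result.scored:
            raise ValueError(
                f"record {result.record_id!r} is not scored; exclude not-assessable "
                "results before summarising"
            )
        totals[entity] += 1
        if result.final is not None and result.final >= threshold:
            benefit[entity] += 1
    return [
        CohortSummary(
            entity=e,
            n_total=totals[e],
            n_benefit=benefit[e],
            pct_benefit=round_half_up_pct(benefit[e], totals[e]),
            threshold=threshold,
        )
        for e in sorted(totals)
    ]


def tabulate_therapy_classes(records: Sequence[StudyRecord]) -> list[tuple[str, int]]:
    """Counts per therapy-class label, descending (ties by label)."""
    counts = Counter(r.therapy_class for r in records if r.therapy_class is not None)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
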