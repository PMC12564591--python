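"""Social Isolation Index and the four-quadrant disclosure typology.

The isolation score is the unweighted sum of the 15 burden-coded exclusion
indicators (range 0–15); a participant is classified as socially isolated
when the score meets the configured cutoff (default 7).  Note this same sum
is read elsewhere as the "cumulative burden" score — they are one quantity
and one operation here.

Crossing high/low disclosure (Told3Plus) with high/low isolation yields the
four interpretive typology quadrants:

======================  =========  ========
quadrant                told3plus  isolated
======================  =========  ========
adaptive_disclosure     1          0
high_exposure           1          1
concealed_resilient     0          0
hidden_vulnerability    0          1
======================  =========  ========
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .catalog import IndicatorCatalog
from .records import DerivedFlags, ParticipantRecord, ThresholdConfig, derive_flags

#: Quadrant labels in canonical display order.
QUADRANTS = (
    "adaptive_disclosure",
    "high_exposure",
    "concealed_resilient",
    "hidden_vulnerability",
)

_QUADRANT_BY_CELL = {
    (1, 0): "adaptive_disclosure",
    (1, 1): "high_exposure",
    (0, 0): "concealed_resilient",
    (0, 1): "hidden_vulnerability",
}


@dataclass(frozen=True)
class TypologyAssignment:
    pid: str
    quadrant: str


@dataclass(frozen=True)
class TypologyCell:
    count: int
    percent: float  # unrounded percentage of n


def isolation_score(record: ParticipantRecord, catalog: IndicatorCatalog) -> int:
    """Sum of the 15 binary indicators (0–15); also the cumulative burden."""
    record.validate(catalog)
    return sum(record.indicators[iid] for iid in catalog.ids)


def classify_isolated(score: int, config: ThresholdConfig) -> int:
    """1 iff *score* meets the isolation cutoff (inclusive)."""
    if not 0 <= score <= 15:
        raise ValueError(f"score must be in [0, 15], got {score}")
    return int(score >= config.isolation_min)


def assign_typology(flags: DerivedFlags, pid: str = "") -> TypologyAssignment:
    """Map a participant's (told3plus, isolated) cell to its quadrant."""
    return TypologyAssignment(pid=pid, quadrant=_QUADRANT_BY_CELL[(flags.told3plus, flags.isolated)])


def typology_table(
    records: Sequence[ParticipantRecord],
    config: ThresholdConfig,
    catalog: IndicatorCatalog,
) -> dict[str, TypologyCell]:
    """Quadrant counts and percentages over a dataset.

    Percentages are stored unrounded; render with
    :func:`hivburden._util.round_half_away` at the precision needed.
    """
    if not records:
        raise ValueError("typology percentages are undefined for an empty dataset")
    n = len(records)
    counts = {q: 0 for q in QUADRANTS}
    for rec in records:
        flags = derive_flags(rec, config, catalog)
        counts[assign_typology(flags, rec.pid).quadrant] += 1
    return {q: TypologyCell(count=c, percent=100.0 * c / n) for q, c in counts.items()}


def typology_assignments(
    records: Sequence[ParticipantRecord],
    config: ThresholdConfig,
    catalog: IndicatorCatalog,
) -> list[TypologyAssignment]:
    """Per-participant quadrant assignments, preserving input order."""
    return [assign_typology(derive_flags(r, config, catalog), r.pid) for r in records]
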