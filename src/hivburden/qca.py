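"""Crisp-set QCA truth tables over binary conditions and outcomes.

Cases (participants) sharing an identical vector of binary condition values
form a configuration; the truth table lists each observed configuration with
its case count and, for each outcome indicator, the number and share of
cases endorsing it.  The within-configuration share is the *consistency*
printed as a percentage in the study's tables; *coverage* (the share of all
outcome cases captured by a configuration) goes beyond the printed tables
and is provided as standard csQCA practice.

Boolean minimisation (Quine–McCluskey and friends) is deliberately absent:
the analysis reports raw truth tables only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._util import round_half_away
from .catalog import IndicatorCatalog
from .records import FLAG_FIELDS, ParticipantRecord, ThresholdConfig, derive_flags


@dataclass(frozen=True)
class ConditionSet:
    """An ordered selection of 2–5 derived-flag names used as QCA conditions."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 2 <= len(self.names) <= 5:
            raise ValueError("a condition set must have between 2 and 5 conditions")
        if len(set(self.names)) != len(self.names):
            raise ValueError("condition names must be distinct")
        unknown = [n for n in self.names if n not in FLAG_FIELDS]
        if unknown:
            raise ValueError(f"unknown condition name(s) {unknown}; choose from {FLAG_FIELDS}")


@dataclass(frozen=True)
class OutcomeTally:
    count: int
    percent: float  # unrounded 100*count/row count


@dataclass(frozen=True)
class TruthTableRow:
    configuration: tuple[int, ...]
    count: int
    outcomes: dict[str, OutcomeTally]


@dataclass
class TruthTable:
    conditions: ConditionSet
    outcomes: tuple[str, ...]
    rows: list[TruthTableRow]
    n_total: int
    min_freq: int = 1
    # analysis context, kept so coverage can re-derive flags consistently
    config: ThresholdConfig = field(default_factory=ThresholdConfig)
    catalog: IndicatorCatalog | None = None

    def row(self, configuration: Sequence[int]) -> TruthTableRow:
        cfg = tuple(int(b) for b in configuration)
        for r in self.rows:
            if r.configuration == cfg:
                return r
        raise KeyError(f"configuration {cfg} not present (unobserved or below min_freq)")


def build_truth_table(
    records: Sequence[ParticipantRecord],
    config: ThresholdConfig,
    catalog: IndicatorCatalog,
    conditions: ConditionSet,
    outcomes: Sequence[str],
    min_freq: int = 1,
) -> TruthTable:
    """Tally one row per observed configuration with count >= *min_freq*.

    Rows are sorted lexicographically by configuration (0 before 1, the
    leftmost condition most significant), matching the published table
    layout.  Unobserved configurations (logical remainders) are omitted.
    """
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    unknown = [o for o in outcomes if o not in catalog.ids]
    if unknown:
        raise ValueError(f"unknown outcome indicator(s): {unknown}")

    groups: dict[tuple[int, ...], list[ParticipantRecord]] = {}
    for rec in records:
        flags = derive_flags(rec, config, catalog)
        key = tuple(getattr(flags, name) for name in conditions.names)
        groups.setdefault(key, []).append(rec)

    rows = []
    for key in sorted(groups):
        members = groups[key]
        if len(members) < min_freq:
            continue
        n = len(members)
        tallies = {}
        for oid in outcomes:
            c = sum(m.indicators[oid] for m in members)
            tallies[oid] = OutcomeTally(count=c, percent=100.0 * c / n)
        rows.append(TruthTableRow(configuration=key, count=n, outcomes=tallies))
    return TruthTable(
        conditions=conditions,
        outcomes=tuple(outcomes),
        rows=rows,
        n_total=len(records),
        min_freq=min_freq,
        config=config,
        catalog=catalog,
    )


def consistency(row: TruthTableRow, outcome: str) -> float:
    """Share of the row's cases endorsing *outcome*, in [0, 1]."""
    if outcome not in row.outcomes:
        raise KeyError(f"outcome {outcome!r} not tallied in this row")
    return row.outcomes[outcome].count / row.count


def coverage(
    table: TruthTable,
    configuration: Sequence[int],
    outcome: str,
    records: Sequence[ParticipantRecord],
) -> float:
    """Share of all outcome cases falling inside *configuration*, in [0, 1].

    Undefined (raises) when the outcome is never observed in *records*.
    """
    if table.catalog is None:
        raise ValueError("truth table lacks its catalog context")
    cfg = tuple(int(b) for b in configuration)
    outcome_total = 0
    joint = 0
    for rec in records:
        flags = derive_flags(rec, table.config, table.catalog)
        has_outcome = rec.indicators[outcome] == 1
        outcome_total += has_outcome
        key = tuple(getattr(flags, name) for name in table.conditions.names)
        joint += has_outcome and key == cfg
    if outcome_total == 0:
        raise ValueError(f"coverage undefined: outcome {outcome!r} never observed")
    return joint / outcome_total


def identify_consistent(
    table: TruthTable, outcome: str, threshold: float
) -> list[TruthTableRow]:
    """Rows whose consistency for *outcome* is >= *threshold*.

    The returned rows carry their case counts so that configurations resting
    on one or two cases remain interpretable.  No default threshold is
    applied: it must be chosen explicitly.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    return [r for r in table.rows if consistency(r, outcome) >= threshold]


def render_table(table: TruthTable) -> "pd.DataFrame":
    """Truth table as a DataFrame with 'count (pct%)' outcome cells.

    Percentages print with one decimal, ties rounded away from zero
    (66.666…% -> '66.7%').
    """
    import pandas as pd

    rows = []
    for r in table.rows:
        row: dict[str, object] = {name: v for name, v in zip(table.conditions.names, r.configuration)}
        row["count"] = r.count
        for oid in table.outcomes:
            t = r.outcomes[oid]
            row[oid] = f"{t.count} ({round_half_away(t.percent, 1):.1f}%)"
        rows.append(row)
    return pd.DataFrame(rows)
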