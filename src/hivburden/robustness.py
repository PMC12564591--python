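"""Threshold robustness: re-run the typology and truth tables under stricter cutoffs.

Raising the disclosure cutoff (e.g. 3 -> 4 people told) or the isolation
cutoff (e.g. 7 -> 8) can only move participants from high- to low-disclosure
and from isolated to not-isolated — the report records both typologies, both
sets of truth tables, per-row consistency changes, and the list of
participants whose quadrant changed, so the "relative positions remain
stable" reading can be checked as: nobody moves against the monotone
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .catalog import IndicatorCatalog
from .indices import TypologyCell, typology_assignments, typology_table
from .qca import ConditionSet, TruthTable, build_truth_table
from .records import ParticipantRecord, ThresholdConfig


@dataclass(frozen=True)
class QuadrantMove:
    pid: str
    baseline_quadrant: str
    alternate_quadrant: str


@dataclass(frozen=True)
class ConsistencyDelta:
    """Consistency change for one configuration/outcome between threshold sets.

    ``baseline`` or ``alternate`` is None when the configuration is absent
    under that threshold set (cases migrated to another configuration).
    """

    conditions: tuple[str, ...]
    configuration: tuple[int, ...]
    outcome: str
    baseline: float | None
    alternate: float | None


@dataclass
class RobustnessReport:
    baseline_config: ThresholdConfig
    alternate_config: ThresholdConfig
    typology_baseline: dict[str, TypologyCell]
    typology_alternate: dict[str, TypologyCell]
    tables_baseline: dict[tuple[str, ...], TruthTable]
    tables_alternate: dict[tuple[str, ...], TruthTable]
    consistency_deltas: list[ConsistencyDelta]
    moves: list[QuadrantMove]

    def to_dict(self) -> dict:
        def _cfg(c: ThresholdConfig) -> dict:
            return {
                "disclosure_min": c.disclosure_min,
                "isolation_min": c.isolation_min,
            }

        def _typ(t: dict[str, TypologyCell]) -> dict:
            return {q: {"count": c.count, "percent": c.percent} for q, c in t.items()}

        return {
            "baseline_config": _cfg(self.baseline_config),
            "alternate_config": _cfg(self.alternate_config),
            "typology_baseline": _typ(self.typology_baseline),
            "typology_alternate": _typ(self.typology_alternate),
            "consistency_deltas": [
                {
                    "conditions": list(d.conditions),
                    "configuration": list(d.configuration),
                    "outcome": d.outcome,
                    "baseline": d.baseline,
                    "alternate": d.alternate,
                }
                for d in self.consistency_deltas
            ],
            "moves": [
                {
                    "pid": m.pid,
                    "baseline_quadrant": m.baseline_quadrant,
                    "alternate_quadrant": m.alternate_quadrant,
                }
                for m in self.moves
            ],
        }


def run_robustness(
    records: Sequence[ParticipantRecord],
    catalog: IndicatorCatalog,
    baseline: ThresholdConfig,
    alternate: ThresholdConfig,
    condition_sets: Sequence[ConditionSet],
    outcomes: Sequence[str],
    allow_looser: bool = False,
) -> RobustnessReport:
    """Compare the typology and truth tables under two threshold configs.

    By default the alternate must be at least as strict as the baseline on
    both cutoffs (the intended use); pass ``allow_looser=True`` to override.
    """
    stricter = (
        alternate.disclosure_min >= baseline.disclosure_min
        and alternate.isolation_min >= baseline.isolation_min
    )
    if not stricter and not allow_looser:
        raise ValueError(
            "alternate thresholds must be >= baseline (stricter); "
            "pass allow_looser=True to override"
        )

    typ_base = typology_table(records, baseline, catalog)
    typ_alt = typology_table(records, alternate, catalog)
    assign_base = {a.pid: a.quadrant for a in typology_assignments(records, baseline, catalog)}
    assign_alt = {a.pid: a.quadrant for a in typology_assignments(records, alternate, catalog)}
    moves = [
        QuadrantMove(pid=p, baseline_quadrant=assign_base[p], alternate_quadrant=assign_alt[p])
        for p in assign_base
        if assign_base[p] != assign_alt[p]
    ]

    tables_base: dict[tuple[str, ...], TruthTable] = {}
    tables_alt: dict[tuple[str, ...], TruthTable] = {}
    deltas: list[ConsistencyDelta] = []
    for cs in condition_sets:
        tb = build_truth_table(records, baseline, catalog, cs, outcomes)
        ta = build_truth_table(records, alternate, catalog, cs, outcomes)
        tables_base[cs.names] = tb
        tables_alt[cs.names] = ta
        cfgs = sorted(
            {r.configuration for r in tb.rows} | {r.configuration for r in ta.rows}
        )
        by_cfg_b = {r.configuration: r for r in tb.rows}
        by_cfg_a = {r.configuration: r for r in ta.rows}
        for cfg in cfgs:
            for oid in outcomes:
                b = by_cfg_b.get(cfg)
                a = by_cfg_a.get(cfg)
                deltas.append(
                    ConsistencyDelta(
                        conditions=cs.names,
                        configuration=cfg,
                        outcome=oid,
                        baseline=(b.outcomes[oid].count / b.count) if b else None,
                        alternate=(a.outcomes[oid].count / a.count) if a else None,
                    )
                )
    return RobustnessReport(
        baseline_config=baseline,
        alternate_config=alternate,
        typology_baseline=typ_base,
        typology_alternate=typ_alt,
        tables_baseline=tables_base,
        tables_alternate=tables_alt,
        consistency_deltas=deltas,
        moves=moves,
    )
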