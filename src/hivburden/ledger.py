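"""The constraint ledger: every published marginal the fixture must satisfy.

The study's 17-respondent dataset is not redistributed here; instead every
count, configuration tally, and rounded group mean printed in its tables and
results text is compiled into a machine-readable ledger of constraints.  A
reconstructed fixture is valid exactly when every entry checks true, and the
ledger doubles as an audit trail: each entry carries the statistic, its
target value, and a citation to the table or section it was read from.

The check functions are deliberately brute-force (plain loops over raw
fields) and never call the analysis pipeline, so that pipeline and ledger
remain two independent routes to the same numbers.

Rounded means are encoded as integer-sum constraints via rounding inversion
(e.g. a printed group mean of 9.3 over 9 members forces the integer sum 84,
the unique integer s with round(s/9, 1) == 9.3), which keeps feasibility
checks exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

from .catalog import OUTCOME_IDS, IndicatorCatalog
from .records import ParticipantRecord, ThresholdConfig

# ---------------------------------------------------------------------------
# Published truth tables: configuration -> (count, per-outcome counts).
# Conditions for the identity table: (told3plus, informed, lgb, straight);
# for the race table: (told3plus, informed, black, white).

TABLE_IDENTITY: dict[tuple[int, int, int, int], dict[str, int]] = {
    (0, 0, 0, 1): {"count": 1, "family_rejects": 0, "friends_reject": 0, "called_names": 0, "work_unfair": 0, "moved_stigma": 0},
    (0, 0, 1, 0): {"count": 6, "family_rejects": 3, "friends_reject": 3, "called_names": 4, "work_unfair": 1, "moved_stigma": 3},
    (1, 0, 0, 1): {"count": 1, "family_rejects": 0, "friends_reject": 0, "called_names": 0, "work_unfair": 0, "moved_stigma": 0},
    (1, 1, 0, 1): {"count": 2, "family_rejects": 2, "friends_reject": 2, "called_names": 2, "work_unfair": 2, "moved_stigma": 1},
    (1, 1, 1, 0): {"count": 7, "family_rejects": 3, "friends_reject": 3, "called_names": 5, "work_unfair": 4, "moved_stigma": 3},
}

TABLE_RACE: dict[tuple[int, int, int, int], dict[str, int]] = {
    (0, 0, 0, 1): {"count": 1, "family_rejects": 0, "friends_reject": 1, "called_names": 1, "work_unfair": 0, "moved_stigma": 0},
    (0, 0, 1, 0): {"count": 6, "family_rejects": 3, "friends_reject": 2, "called_names": 3, "work_unfair": 1, "moved_stigma": 3},
    (1, 0, 1, 0): {"count": 1, "family_rejects": 0, "friends_reject": 0, "called_names": 0, "work_unfair": 0, "moved_stigma": 0},
    (1, 1, 0, 0): {"count": 1, "family_rejects": 0, "friends_reject": 0, "called_names": 0, "work_unfair": 0, "moved_stigma": 0},
    (1, 1, 0, 1): {"count": 2, "family_rejects": 1, "friends_reject": 1, "called_names": 2, "work_unfair": 2, "moved_stigma": 2},
    (1, 1, 1, 0): {"count": 6, "family_rejects": 4, "friends_reject": 4, "called_names": 5, "work_unfair": 4, "moved_stigma": 2},
}

#: Published heatmap cells: (flag group, indicator) -> count within the group.
HEATMAP_CELLS: dict[tuple[str, str], int] = {
    ("told3plus", "called_names"): 7,
    ("told3plus", "family_rejects"): 5,
    ("told3plus", "work_unfair"): 6,
    ("informed_sex_partners", "called_names"): 7,
    ("informed_sex_partners", "family_rejects"): 5,
    ("informed_sex_partners", "work_unfair"): 6,
    ("gay_or_lesbian", "called_names"): 9,
    ("gay_or_lesbian", "family_rejects"): 6,
    ("black", "called_names"): 8,
    ("black", "family_rejects"): 7,
    ("white", "called_names"): 3,
}

#: Integer burden sums per disclosure group, inverted from the printed
#: one-decimal means (9.3 over 9 -> 84; 6.6 over 7 -> 46; 3.0 over 1 -> 3).
BURDEN_SUMS = {"high_partner": 84, "low_nopartner": 46, "high_nopartner": 3}

TYPOLOGY_COUNTS = {
    "adaptive_disclosure": 4,
    "high_exposure": 6,
    "concealed_resilient": 3,
    "hidden_vulnerability": 4,
}

IDENTITY_COUNTS = {"gay_lesbian": 11, "bisexual": 2, "straight": 4}
RACE_COUNTS = {"black": 13, "white": 3, "other": 1}
DISCLOSURE_JOINT = {(1, 1): 9, (1, 0): 1, (0, 0): 7, (0, 1): 0}
N_TOTAL = 17
ISOLATED_COUNT = 10


@dataclass(frozen=True)
class ConstraintEntry:
    """One machine-checkable constraint on a candidate record list."""

    id: str
    description: str
    scope: str
    statistic: str  # "count" | "sum"
    target: int
    provenance: str
    check: Callable[[Sequence[ParticipantRecord], IndicatorCatalog, ThresholdConfig], int]

    def evaluate(
        self,
        records: Sequence[ParticipantRecord],
        catalog: IndicatorCatalog,
        config: ThresholdConfig,
    ) -> tuple[bool, int]:
        actual = self.check(records, catalog, config)
        return actual == self.target, actual


@dataclass(frozen=True)
class ConstraintLedger:
    entries: tuple[ConstraintEntry, ...]

    def __getitem__(self, entry_id: str) -> ConstraintEntry:
        for e in self.entries:
            if e.id == entry_id:
                return e
        raise KeyError(entry_id)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def evaluate(
        self,
        records: Sequence[ParticipantRecord],
        catalog: IndicatorCatalog,
        config: ThresholdConfig | None = None,
    ) -> list[dict]:
        """Check every entry; returns one result dict per entry."""
        config = config or ThresholdConfig()
        out = []
        for e in self.entries:
            ok, actual = e.evaluate(records, catalog, config)
            out.append(
                {
                    "id": e.id,
                    "description": e.description,
                    "scope": e.scope,
                    "statistic": e.statistic,
                    "target": e.target,
                    "actual": actual,
                    "passed": ok,
                    "provenance": e.provenance,
                }
            )
        return out

    def violations(
        self,
        records: Sequence[ParticipantRecord],
        catalog: IndicatorCatalog,
        config: ThresholdConfig | None = None,
    ) -> list[str]:
        return [r["id"] for r in self.evaluate(records, catalog, config) if not r["passed"]]

    def to_json(
        self,
        path: str | Path,
        records: Sequence[ParticipantRecord] | None = None,
        catalog: IndicatorCatalog | None = None,
        config: ThresholdConfig | None = None,
    ) -> None:
        """Export all constraints, optionally with pass/fail against a dataset."""
        if records is not None and catalog is not None:
            payload = self.evaluate(records, catalog, config)
        else:
            payload = [
                {
                    "id": e.id,
                    "description": e.description,
                    "scope": e.scope,
                    "statistic": e.statistic,
                    "target": e.target,
                    "provenance": e.provenance,
                }
                for e in self.entries
            ]
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Brute-force primitives (raw fields only; no pipeline calls).


def _score(rec: ParticipantRecord, catalog: IndicatorCatalog) -> int:
    return sum(rec.indicators[i] for i in catalog.ids)


def _flag(rec: ParticipantRecord, name: str, config: ThresholdConfig, catalog: IndicatorCatalog) -> int:
    if name == "told3plus":
        return int(rec.people_told >= config.disclosure_min)
    if name == "informed_sex_partners":
        return int(rec.informed_sex_partners)
    if name == "lgb":
        return int(rec.sexual_identity in ("gay_lesbian", "bisexual"))
    if name == "straight":
        return int(rec.sexual_identity == "straight")
    if name == "gay_or_lesbian":
        return int(rec.sexual_identity == "gay_lesbian")
    if name == "black":
        return int(rec.race == "black")
    if name == "white":
        return int(rec.race == "white")
    if name == "isolated":
        return int(_score(rec, catalog) >= config.isolation_min)
    raise KeyError(name)


def _make_count(predicate):
    def check(records, catalog, config):
        return sum(1 for r in records if predicate(r, catalog, config))

    return check


def compile_ledger() -> ConstraintLedger:
    """Compile every usable published marginal into a constraint ledger.

    Deliberately excluded (documented inconsistencies / vagueness): the
    stricter-threshold claim that no participant remains isolated at cutoff
    8 (it contradicts the high-disclosure group's burden sum of 84 over 9),
    and the "about half" prose for straight participants' heatmap cells.
    """
    entries: list[ConstraintEntry] = []

    entries.append(
        ConstraintEntry(
            id="n_total",
            description="number of PLHIV respondents",
            scope="all",
            statistic="count",
            target=N_TOTAL,
            provenance="study design (n=17 PLHIV)",
            check=lambda rs, cat, cfg: len(rs),
        )
    )

    for ident, n in IDENTITY_COUNTS.items():
        entries.append(
            ConstraintEntry(
                id=f"identity_{ident}",
                description=f"respondents with sexual_identity={ident}",
                scope="all",
                statistic="count",
                target=n,
                provenance="identity margins of the identity truth table + heatmap group sizes",
                check=_make_count(
                    lambda r, cat, cfg, ident=ident: r.sexual_identity == ident
                ),
            )
        )
    for race, n in RACE_COUNTS.items():
        entries.append(
            ConstraintEntry(
                id=f"race_{race}",
                description=f"respondents with race={race}",
                scope="all",
                statistic="count",
                target=n,
                provenance="race margins of the race truth table + heatmap group sizes",
                check=_make_count(lambda r, cat, cfg, race=race: r.race == race),
            )
        )

    for (t, i), n in DISCLOSURE_JOINT.items():
        entries.append(
            ConstraintEntry(
                id=f"disclosure_joint_{t}{i}",
                description=f"respondents with told3plus={t}, informed_sex_partners={i}",
                scope="all",
                statistic="count",
                target=n,
                provenance="burden-by-disclosure-group figure (group sizes 9/1/7/0)",
                check=_make_count(
                    lambda r, cat, cfg, t=t, i=i: _flag(r, "told3plus", cfg, cat) == t
                    and r.informed_sex_partners == i
                ),
            )
        )

    entries.append(
        ConstraintEntry(
            id="isolated_count",
            description="respondents with isolation score >= cutoff",
            scope="all",
            statistic="count",
            target=ISOLATED_COUNT,
            provenance="index construction text: 10 of 17 (59%) isolated at cutoff 7",
            check=_make_count(
                lambda r, cat, cfg: _score(r, cat) >= cfg.isolation_min
            ),
        )
    )

    quadrant_cells = {
        "adaptive_disclosure": (1, 0),
        "high_exposure": (1, 1),
        "concealed_resilient": (0, 0),
        "hidden_vulnerability": (0, 1),
    }
    for q, n in TYPOLOGY_COUNTS.items():
        t, iso = quadrant_cells[q]
        entries.append(
            ConstraintEntry(
                id=f"typology_{q}",
                description=f"respondents in typology quadrant {q}",
                scope="all",
                statistic="count",
                target=n,
                provenance="typology figure quadrant counts (4/6/3/4)",
                check=_make_count(
                    lambda r, cat, cfg, t=t, iso=iso: _flag(r, "told3plus", cfg, cat) == t
                    and int(_score(r, cat) >= cfg.isolation_min) == iso
                ),
            )
        )

    group_cells = {"high_partner": (1, 1), "high_nopartner": (1, 0), "low_nopartner": (0, 0)}
    for g, total in BURDEN_SUMS.items():
        t, i = group_cells[g]

        def sum_check(records, catalog, config, t=t, i=i):
            return sum(
                _score(r, catalog)
                for r in records
                if _flag(r, "told3plus", config, catalog) == t and r.informed_sex_partners == i
            )

        entries.append(
            ConstraintEntry(
                id=f"burden_sum_{g}",
                description=f"total burden score of disclosure group {g} "
                "(integer inversion of the printed one-decimal mean)",
                scope=f"disclosure group {g}",
                statistic="sum",
                target=total,
                provenance="mean cumulative burden by disclosure group (9.3 / 6.6 / 3.0)",
                check=sum_check,
            )
        )

    table_specs = (
        ("identity", ("told3plus", "informed_sex_partners", "lgb", "straight"), TABLE_IDENTITY),
        ("race", ("told3plus", "informed_sex_partners", "black", "white"), TABLE_RACE),
    )
    for label, cond_names, table in table_specs:
        for cfg_bits, cells in table.items():
            bits = "".join(str(b) for b in cfg_bits)

            def members(records, catalog, config, cond_names=cond_names, cfg_bits=cfg_bits):
                return [
                    r
                    for r in records
                    if tuple(_flag(r, n, config, catalog) for n in cond_names) == cfg_bits
                ]

            entries.append(
                ConstraintEntry(
                    id=f"{label}_cfg_{bits}_count",
                    description=f"{label} table: case count of configuration {cfg_bits}",
                    scope=f"configuration {cfg_bits} of ({', '.join(cond_names)})",
                    statistic="count",
                    target=cells["count"],
                    provenance=f"{label} truth table, Count column",
                    check=lambda rs, cat, cfg, members=members: len(members(rs, cat, cfg)),
                )
            )
            for oid in OUTCOME_IDS:
                entries.append(
                    ConstraintEntry(
                        id=f"{label}_cfg_{bits}_{oid}",
                        description=f"{label} table: {oid} cases in configuration {cfg_bits}",
                        scope=f"configuration {cfg_bits} of ({', '.join(cond_names)})",
                        statistic="count",
                        target=cells[oid],
                        provenance=f"{label} truth table, {oid} column",
                        check=lambda rs, cat, cfg, members=members, oid=oid: sum(
                            r.indicators[oid] for r in members(rs, cat, cfg)
                        ),
                    )
                )

    for (flag_name, iid), n in HEATMAP_CELLS.items():
        entries.append(
            ConstraintEntry(
                id=f"hm_{flag_name}_{iid}",
                description=f"heatmap: {iid} cases within group {flag_name}=1",
                scope=f"group {flag_name}=1",
                statistic="count",
                target=n,
                provenance="group-by-indicator heatmap cell",
                check=_make_count(
                    lambda r, cat, cfg, flag_name=flag_name, iid=iid: _flag(
                        r, flag_name, cfg, cat
                    )
                    == 1
                    and r.indicators[iid] == 1
                ),
            )
        )

    return ConstraintLedger(entries=tuple(entries))
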