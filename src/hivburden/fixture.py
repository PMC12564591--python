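"""Constraint-solved reconstruction of the 17-respondent survey fixture.

The published tables fix far more than headline counts: joint configuration
tallies by identity and by race, per-configuration outcome counts, heatmap
cells, quadrant counts, and integer burden sums recovered from rounded
means.  :func:`build_fixture` reconstructs a participant-level dataset that
satisfies every entry of the compiled constraint ledger, by staged seeded
backtracking:

1. **Skeleton** — participants are allocated to disclosure cells
   (told3plus × informed) with identity-class and race-class margins taken
   from the two truth tables; the joint identity × race allocation inside a
   cell is a small contingency table, enumerated and tried in seeded order.
2. **Outcome bits** — within each cell, each of the five outcome indicators
   is a transportation problem (row sums from the identity table, column
   sums from the race table, cell caps from the joint allocation); a
   feasible assignment is chosen in seeded order and bits are placed on a
   shared per-cell prefix so that zero-rows concentrate on the same people.
3. **Identity refinement** — the bisexual respondents are chosen among LGB
   members whose called-names and family-rejection bits are both 0 (the
   only placement compatible with the gay/lesbian heatmap cells).
4. **Scores** — isolated-vs-not splits and integer score vectors are drawn
   per disclosure group to hit the group burden sums and quadrant counts,
   respecting per-person bounds (score >= outcome bits set, score <= outcome
   bits + 10 free indicators).
5. **Free indicators** — each person's remaining score is realised by a
   seeded choice among the ten non-outcome indicators, and disclosure
   counts compatible with the Told3Plus flag are drawn ({0,1,2} vs {3..10}).

Every candidate is verified against the full ledger before being returned;
output is deterministic for a given seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .catalog import OUTCOME_IDS, IndicatorCatalog
from .ledger import ConstraintLedger
from .records import ParticipantRecord, ThresholdConfig

_ID_CLASSES = ("lgb", "straight")
_RACE_CLASSES = ("black", "white", "other")
_QUAD_BITS = {"lgb": (1, 0), "straight": (0, 1)}
_RACE_BITS = {"black": (1, 0), "white": (0, 1), "other": (0, 0)}

_MAX_ATTEMPTS = 64


class FixtureInfeasibleError(RuntimeError):
    """No candidate satisfying the ledger was found.

    ``violations`` lists the smallest set of violated constraint ids seen
    across all attempts.
    """

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            f"fixture search exhausted; smallest violated constraint set: {violations}"
        )


@dataclass
class _Person:
    told3plus: int
    informed: int
    idclass: str
    raceclass: str
    outcome_bits: dict[str, int] = field(default_factory=dict)
    bisexual: bool = False
    score: int = 0


# ---------------------------------------------------------------------------
# Small exact enumerators.


def _tables(row_sums: Sequence[int], col_sums: Sequence[int], caps=None):
    """All non-negative integer matrices with given margins (and cell caps)."""
    n_rows, n_cols = len(row_sums), len(col_sums)
    if sum(row_sums) != sum(col_sums):
        return
    grid = [[0] * n_cols for _ in range(n_rows)]

    def fill_row(r: int, remaining_cols: list[int]):
        if r == n_rows:
            if all(c == 0 for c in remaining_cols):
                yield [row[:] for row in grid]
            return

        def fill_cell(c: int, left: int):
            if c == n_cols - 1:
                cap = caps[r][c] if caps else left
                if left <= min(remaining_cols[c], cap):
                    grid[r][c] = left
                    remaining_cols[c] -= left
                    yield from fill_row(r + 1, remaining_cols)
                    remaining_cols[c] += left
                return
            cap = caps[r][c] if caps else left
            for v in range(min(left, remaining_cols[c], cap) + 1):
                grid[r][c] = v
                remaining_cols[c] -= v
                yield from fill_cell(c + 1, left - v)
                remaining_cols[c] += v

        yield from fill_cell(0, row_sums[r])

    yield from fill_row(0, list(col_sums))


def _shuffled(items, rng: np.random.Generator) -> list:
    items = list(items)
    rng.shuffle(items)
    return items


# ---------------------------------------------------------------------------
# Stage 1–2: per-cell structure and outcome bits.


def _cell_margins(targets: dict[str, int], t: int, i: int):
    """Identity/race class margins and outcome sums for one disclosure cell."""

    def bits_key(table: str, quad: tuple[int, int], suffix: str) -> str:
        return f"{table}_cfg_{t}{i}{quad[0]}{quad[1]}_{suffix}"

    id_margin = {
        idc: targets.get(bits_key("identity", _QUAD_BITS[idc], "count"), 0)
        for idc in _ID_CLASSES
    }
    race_margin = {
        rc: targets.get(bits_key("race", _RACE_BITS[rc], "count"), 0)
        for rc in _RACE_CLASSES
    }
    id_out = {
        idc: {o: targets.get(bits_key("identity", _QUAD_BITS[idc], o), 0) for o in OUTCOME_IDS}
        for idc in _ID_CLASSES
    }
    race_out = {
        rc: {o: targets.get(bits_key("race", _RACE_BITS[rc], o), 0) for o in OUTCOME_IDS}
        for rc in _RACE_CLASSES
    }
    return id_margin, race_margin, id_out, race_out


def _solve_cell(t: int, i: int, targets: dict[str, int], rng: np.random.Generator):
    """People of one disclosure cell with identity/race classes and outcome bits."""
    id_margin, race_margin, id_out, race_out = _cell_margins(targets, t, i)
    row_sums = [id_margin[idc] for idc in _ID_CLASSES]
    col_sums = [race_margin[rc] for rc in _RACE_CLASSES]
    if sum(row_sums) == 0:
        return []

    for joint in _shuffled(_tables(row_sums, col_sums), rng):
        placements: dict[str, list[list[int]]] = {}
        feasible = True
        for oid in OUTCOME_IDS:
            o_rows = [id_out[idc][oid] for idc in _ID_CLASSES]
            o_cols = [race_out[rc][oid] for rc in _RACE_CLASSES]
            options = list(_tables(o_rows, o_cols, caps=joint))
            if not options:
                feasible = False
                break
            placements[oid] = options[int(rng.integers(len(options)))]
        if not feasible:
            continue

        people: list[_Person] = []
        for r, idc in enumerate(_ID_CLASSES):
            for c, rc in enumerate(_RACE_CLASSES):
                m = joint[r][c]
                cell_people = [
                    _Person(told3plus=t, informed=i, idclass=idc, raceclass=rc)
                    for _ in range(m)
                ]
                # bits of every outcome go to the same prefix, so zero
                # profiles concentrate on the tail of the cell
                for oid in OUTCOME_IDS:
                    ones = placements[oid][r][c]
                    for p in cell_people[:ones]:
                        p.outcome_bits[oid] = 1
                    for p in cell_people[ones:]:
                        p.outcome_bits.setdefault(oid, 0)
                people.extend(cell_people)
        return people
    return None


# ---------------------------------------------------------------------------
# Stage 4: scores.


def _assign_scores(
    people: list[_Person],
    total: int | None,
    n_isolated: int,
    isolation_min: int,
    n_free: int,
    rng: np.random.Generator,
    max_subsets: int = 200,
) -> bool:
    """Choose integer scores: *n_isolated* at or above the cutoff, the rest
    below, summing to *total*, each within [outcome bits, outcome bits + free
    indicators].  Mutates ``person.score``; returns False when infeasible."""
    m = len(people)
    if not 0 <= n_isolated <= m:
        return False
    mins = [sum(p.outcome_bits.values()) for p in people]
    order = _shuffled(range(m), rng)
    for subset in itertools.islice(itertools.combinations(order, n_isolated), max_subsets):
        iso = set(subset)
        lo, hi = [], []
        ok = True
        for j in range(m):
            if j in iso:
                l, h = max(isolation_min, mins[j]), min(15, mins[j] + n_free)
            else:
                l, h = mins[j], min(isolation_min - 1, mins[j] + n_free)
            if l > h:
                ok = False
                break
            lo.append(l)
            hi.append(h)
        if not ok:
            continue
        target = total if total is not None else sum(lo)
        if not sum(lo) <= target <= sum(hi):
            continue
        scores = lo[:]
        need = target - sum(lo)
        while need > 0:
            slack = [j for j in range(m) if scores[j] < hi[j]]
            j = slack[int(rng.integers(len(slack)))]
            scores[j] += 1
            need -= 1
        for j, p in enumerate(people):
            p.score = scores[j]
        return True
    return False


# ---------------------------------------------------------------------------
# Driver.


def _attempt(
    targets: dict[str, int],
    catalog: IndicatorCatalog,
    config: ThresholdConfig,
    rng: np.random.Generator,
) -> list[ParticipantRecord] | None:
    cells = [(1, 1), (1, 0), (0, 1), (0, 0)]
    people: list[_Person] = []
    by_cell: dict[tuple[int, int], list[_Person]] = {}
    for t, i in cells:
        solved = _solve_cell(t, i, targets, rng)
        if solved is None:
            return None
        by_cell[(t, i)] = solved
        people.extend(solved)

    # bisexual respondents: LGB members with both heatmap-constrained
    # outcome bits at zero (forced by the gay/lesbian cell counts)
    n_bisexual = targets.get("identity_bisexual", 0)
    candidates = [
        p
        for p in people
        if p.idclass == "lgb"
        and p.outcome_bits["called_names"] == 0
        and p.outcome_bits["family_rejects"] == 0
    ]
    if len(candidates) < n_bisexual:
        return None
    for j in rng.choice(len(candidates), size=n_bisexual, replace=False):
        candidates[int(j)].bisexual = True

    # isolated counts per told3plus stratum come from the quadrant targets
    n_free = len(catalog.non_outcome_ids)
    iso_per_stratum = {
        1: targets.get("typology_high_exposure", 0),
        0: targets.get("typology_hidden_vulnerability", 0),
    }
    group_sum_key = {(1, 1): "high_partner", (1, 0): "high_nopartner",
                     (0, 1): "low_partner", (0, 0): "low_nopartner"}
    for t in (1, 0):
        stratum_cells = [(t, 1), (t, 0)]
        sizes = [len(by_cell[c]) for c in stratum_cells]
        k_total = iso_per_stratum[t]
        splits = [
            (k1, k_total - k1)
            for k1 in range(min(sizes[0], k_total) + 1)
            if k_total - k1 <= sizes[1] and k_total - k1 >= 0
        ]
        success = False
        for k1, k0 in _shuffled(splits, rng):
            state = [(p, p.score) for c in stratum_cells for p in by_cell[c]]
            ok = True
            for cell, k in zip(stratum_cells, (k1, k0)):
                total = targets.get(f"burden_sum_{group_sum_key[cell]}")
                if not by_cell[cell]:
                    if total not in (None, 0) or k != 0:
                        ok = False
                        break
                    continue
                if not _assign_scores(
                    by_cell[cell], total, k, config.isolation_min, n_free, rng
                ):
                    ok = False
                    break
            if ok:
                success = True
                break
            for p, s in state:
                p.score = s
        if not success:
            return None

    # realise scores through the free indicators and draw disclosure counts
    free_ids = list(catalog.non_outcome_ids)
    records: list[ParticipantRecord] = []
    order = _shuffled(people, rng)
    for idx, p in enumerate(order, start=1):
        extras = p.score - sum(p.outcome_bits.values())
        if not 0 <= extras <= n_free:
            return None
        chosen = set(
            free_ids[int(j)] for j in rng.choice(n_free, size=extras, replace=False)
        )
        indicators = {iid: p.outcome_bits.get(iid, 0) for iid in OUTCOME_IDS}
        indicators.update({iid: int(iid in chosen) for iid in free_ids})
        if p.told3plus:
            people_told = int(rng.integers(config.disclosure_min, 11))
        else:
            people_told = int(rng.integers(0, config.disclosure_min))
        identity = (
            "straight"
            if p.idclass == "straight"
            else ("bisexual" if p.bisexual else "gay_lesbian")
        )
        records.append(
            ParticipantRecord(
                pid=f"P{idx:02d}",
                people_told=people_told,
                informed_sex_partners=p.informed,
                sexual_identity=identity,
                race=p.raceclass,
                indicators={iid: indicators[iid] for iid in catalog.ids},
            )
        )
    return records


def build_fixture(
    ledger: ConstraintLedger,
    catalog: IndicatorCatalog,
    seed: int,
    config: ThresholdConfig | None = None,
) -> list[ParticipantRecord]:
    """Reconstruct a participant list satisfying every ledger entry.

    Deterministic for a given *seed*.  Raises
    :class:`FixtureInfeasibleError` when the search is exhausted, reporting
    the smallest violated constraint set found.
    """
    config = config or ThresholdConfig()
    targets = {e.id: e.target for e in ledger}
    best_violations: list[str] | None = None
    for attempt in range(_MAX_ATTEMPTS):
        rng = np.random.default_rng([seed, attempt])
        records = _attempt(targets, catalog, config, rng)
        if records is None:
            continue
        violations = ledger.violations(records, catalog, config)
        if not violations:
            return records
        if best_violations is None or len(violations) < len(best_violations):
            best_violations = violations
    raise FixtureInfeasibleError(best_violations or ["<no structurally complete candidate>"])
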