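"""Participant records: domain types, CSV I/O, and derived analysis flags.

A participant record carries the raw survey fields — a disclosure count
(``people_told``), a partner-disclosure flag, sexual identity, race, and the
15 binary exclusion indicators — and :func:`derive_flags` turns them into
the binary analysis variables (Told3Plus, LGB/Straight, Black/White, the
0–15 isolation score and the isolated flag) under a threshold configuration.

Missing data is not modelled: any empty or non-binary cell is a validation
error, mirroring the complete-case reporting of the underlying survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .catalog import IndicatorCatalog

IDENTITY_VALUES = ("gay_lesbian", "bisexual", "straight")
RACE_VALUES = ("black", "white", "other")

#: Fixed CSV columns preceding the indicator block.
BASE_COLUMNS = ("pid", "people_told", "informed_sex_partners", "sexual_identity", "race")


class SchemaError(ValueError):
    """A participants file does not have the expected column layout."""


class ValidationError(ValueError):
    """A record holds an out-of-range or non-binary value."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Analysis thresholds.

    Parameters
    ----------
    disclosure_min
        Minimum number of disclosures counted as "high disclosure"
        (Told3Plus uses 3: disclosed to three or more individuals).
    isolation_min
        Minimum isolation score (of 15) counted as socially isolated
        (default 7: "scored 7 or higher").
    scatter_cap
        Cap applied to the disclosure count on the scatterplot x-axis.
    """

    disclosure_min: int = 3
    isolation_min: int = 7
    scatter_cap: int = 10

    def __post_init__(self) -> None:
        if self.disclosure_min < 1:
            raise ValidationError("disclosure_min must be >= 1")
        if not 0 <= self.isolation_min <= 15:
            raise ValidationError("isolation_min must be in [0, 15]")
        if self.scatter_cap < 1:
            raise ValidationError("scatter_cap must be >= 1")


@dataclass
class ParticipantRecord:
    """One respondent: raw disclosure, identity, and 15 binary indicators."""

    pid: str
    people_told: int
    informed_sex_partners: int
    sexual_identity: str
    race: str
    indicators: dict[str, int]

    def validate(self, catalog: IndicatorCatalog) -> None:
        if self.people_told < 0:
            raise ValidationError(f"{self.pid}: people_told must be >= 0")
        if self.informed_sex_partners not in (0, 1):
            raise ValidationError(f"{self.pid}: informed_sex_partners must be 0/1")
        if self.sexual_identity not in IDENTITY_VALUES:
            raise ValidationError(
                f"{self.pid}: sexual_identity {self.sexual_identity!r} not in {IDENTITY_VALUES}"
            )
        if self.race not in RACE_VALUES:
            raise ValidationError(f"{self.pid}: race {self.race!r} not in {RACE_VALUES}")
        if set(self.indicators) != set(catalog.ids):
            missing = sorted(set(catalog.ids) - set(self.indicators))
            extra = sorted(set(self.indicators) - set(catalog.ids))
            raise ValidationError(
                f"{self.pid}: indicator ids do not match catalog "
                f"(missing={missing}, extra={extra})"
            )
        for iid, v in self.indicators.items():
            if v not in (0, 1):
                raise ValidationError(f"{self.pid}: indicator {iid} has non-binary value {v!r}")


@dataclass(frozen=True)
class DerivedFlags:
    """Binary analysis variables derived from a single record."""

    told3plus: int
    informed_sex_partners: int
    lgb: int
    straight: int
    gay_or_lesbian: int
    black: int
    white: int
    isolation_score: int
    isolated: int


#: DerivedFlags fields usable as QCA conditions / heatmap group definitions.
FLAG_FIELDS = (
    "told3plus",
    "informed_sex_partners",
    "lgb",
    "straight",
    "gay_or_lesbian",
    "black",
    "white",
    "isolated",
)


def derive_flags(
    record: ParticipantRecord, config: ThresholdConfig, catalog: IndicatorCatalog
) -> DerivedFlags:
    """Compute the analysis flags for one record.

    The isolation score is the unweighted sum of the 15 indicators (all
    stored burden-coded, so the sum is also the cumulative burden score).
    """
    record.validate(catalog)
    score = sum(record.indicators[iid] for iid in catalog.ids)
    return DerivedFlags(
        told3plus=int(record.people_told >= config.disclosure_min),
        informed_sex_partners=int(record.informed_sex_partners),
        lgb=int(record.sexual_identity in ("gay_lesbian", "bisexual")),
        straight=int(record.sexual_identity == "straight"),
        gay_or_lesbian=int(record.sexual_identity == "gay_lesbian"),
        black=int(record.race == "black"),
        white=int(record.race == "white"),
        isolation_score=score,
        isolated=int(score >= config.isolation_min),
    )


# ---------------------------------------------------------------------------
# CSV I/O


def _expected_columns(catalog: IndicatorCatalog) -> tuple[str, ...]:
    return BASE_COLUMNS + catalog.ids


def read_participants(path: str | Path, catalog: IndicatorCatalog) -> list[ParticipantRecord]:
    """Read a participants CSV, validating the schema against *catalog*.

    The file must contain exactly the base columns plus one column per
    catalog indicator id; rows are returned in file order.
    """
    df = pd.read_csv(path, dtype={"pid": str})
    expected = _expected_columns(catalog)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    extra = [c for c in df.columns if c not in expected]
    if extra:
        raise SchemaError(f"unexpected column(s): {extra}")
    if df.isna().any().any():
        bad = df[df.isna().any(axis=1)]
        raise ValidationError(f"empty cells in rows: {list(bad['pid'].fillna('<no pid>'))}")

    records: list[ParticipantRecord] = []
    for _, row in df.iterrows():
        pid = str(row["pid"])
        try:
            rec = ParticipantRecord(
                pid=pid,
                people_told=_as_int(row["people_told"], pid, "people_told"),
                informed_sex_partners=_as_int(
                    row["informed_sex_partners"], pid, "informed_sex_partners"
                ),
                sexual_identity=str(row["sexual_identity"]),
                race=str(row["race"]),
                indicators={iid: _as_int(row[iid], pid, iid) for iid in catalog.ids},
            )
        except ValidationError:
            raise
        rec.validate(catalog)
        records.append(rec)
    pids = [r.pid for r in records]
    if len(set(pids)) != len(pids):
        raise ValidationError("duplicate pid values in input")
    return records


def _as_int(value, pid: str, column: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{pid}: column {column} has non-numeric value {value!r}")
    if f != int(f):
        raise ValidationError(f"{pid}: column {column} has non-integer value {value!r}")
    return int(f)


def write_participants(
    records: Sequence[ParticipantRecord],
    path: str | Path,
    catalog: IndicatorCatalog | None = None,
) -> None:
    """Write records to CSV in the canonical column order.

    Round-trips bit-identically through :func:`read_participants`. The
    indicator column order follows *catalog* (default catalog if omitted).
    """
    from .catalog import default_catalog

    catalog = catalog or default_catalog()
    cols = _expected_columns(catalog)
    rows = []
    for rec in records:
        rec.validate(catalog)
        row = {
            "pid": rec.pid,
            "people_told": rec.people_told,
            "informed_sex_partners": rec.informed_sex_partners,
            "sexual_identity": rec.sexual_identity,
            "race": rec.race,
        }
        row.update({iid: rec.indicators[iid] for iid in catalog.ids})
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(cols))
    df.to_csv(path, index=False)
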