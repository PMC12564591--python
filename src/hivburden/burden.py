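"""Burden profiling: group means, domain profiles, heatmap tallies, scatter prep.

Disclosure groups cross breadth (Told3Plus) with relational specificity
(InformedSexPartners):

==================  =========  =====================
group               told3plus  informed_sex_partners
==================  =========  =====================
high_partner        1          1
high_nopartner      1          0
low_partner         0          1
low_nopartner       0          0
==================  =========  =====================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import DOMAINS, IndicatorCatalog
from .indices import isolation_score
from .records import (
    FLAG_FIELDS,
    DerivedFlags,
    ParticipantRecord,
    ThresholdConfig,
    derive_flags,
)

DISCLOSURE_GROUPS = ("high_partner", "high_nopartner", "low_partner", "low_nopartner")

_GROUP_BY_CELL = {
    (1, 1): "high_partner",
    (1, 0): "high_nopartner",
    (0, 1): "low_partner",
    (0, 0): "low_nopartner",
}


@dataclass(frozen=True)
class GroupBurden:
    label: str
    n: int
    mean: float | None  # unrounded; None when the group is empty


@dataclass(frozen=True)
class HeatmapCell:
    count: int
    percent: float | None  # unrounded 100*count/n; None when n == 0


@dataclass(frozen=True)
class GroupProfile:
    """Counts/percentages of every indicator within one flag-defined group."""

    label: str
    n: int
    cells: dict[str, HeatmapCell]


@dataclass(frozen=True)
class DomainProfile:
    """Per-domain mean burden (each in [0, 1]) for one disclosure group."""

    label: str
    n: int
    values: dict[str, float]


@dataclass(frozen=True)
class ScatterRefs:
    x_median: float
    y_threshold: int


def disclosure_group(flags: DerivedFlags) -> str:
    return _GROUP_BY_CELL[(flags.told3plus, flags.informed_sex_partners)]


def group_mean_burden(
    records: Sequence[ParticipantRecord],
    config: ThresholdConfig,
    catalog: IndicatorCatalog,
) -> dict[str, GroupBurden]:
    """Mean cumulative burden (isolation score) per disclosure group.

    Means are kept unrounded; the published one-decimal figures come from
    rounding half away from zero at render time.  Empty groups are reported
    with n=0 and mean None.
    """
    if not records:
        raise ValueError("no records")
    sums = {g: 0 for g in DISCLOSURE_GROUPS}
    ns = {g: 0 for g in DISCLOSURE_GROUPS}
    for rec in records:
        g = disclosure_group(derive_flags(rec, config, catalog))
        sums[g] += isolation_score(rec, catalog)
        ns[g] += 1
    return {
        g: GroupBurden(label=g, n=ns[g], mean=(sums[g] / ns[g] if ns[g] else None))
        for g in DISCLOSURE_GROUPS
    }


def domain_profile(
    records: Sequence[ParticipantRecord],
    group: str,
    config: ThresholdConfig,
    catalog: IndicatorCatalog,
) -> DomainProfile:
    """Seven-domain burden profile of one disclosure group.

    For each domain the value is the mean over group members of their
    within-domain indicator mean (each member's domain score is the fraction
    of that domain's items they endorse), so values lie in [0, 1].
    """
    if group not in DISCLOSURE_GROUPS:
        raise ValueError(f"unknown disclosure group {group!r}")
    members = [
        r for r in records if disclosure_group(derive_flags(r, config, catalog)) == group
    ]
    if not members:
        raise ValueError(f"disclosure group {group!r} is empty")
    values: dict[str, float] = {}
    for domain in DOMAINS:
        items = catalog.domain_items(domain)
        per_member = [sum(m.indicators[i] for i in items) / len(items) for m in members]
        values[domain] = float(np.mean(per_member))
    return DomainProfile(label=group, n=len(members), values=values)


def indicator_heatmap(
    records: Sequence[ParticipantRecord],
    config: ThresholdConfig,
    catalog: IndicatorCatalog,
    group_defs: Sequence[str] = (
        "told3plus",
        "informed_sex_partners",
        "gay_or_lesbian",
        "straight",
        "black",
        "white",
    ),
) -> list[GroupProfile]:
    """Indicator counts/percentages within each flag-defined group.

    Each *group_def* names a :class:`DerivedFlags` field; membership is
    flag == 1.  An empty group yields n=0 cells with percent None.
    """
    for g in group_defs:
        if g not in FLAG_FIELDS:
            raise ValueError(f"group_def {g!r} is not a derived flag (choose from {FLAG_FIELDS})")
    flagged = [(rec, derive_flags(rec, config, catalog)) for rec in records]
    profiles = []
    for g in group_defs:
        members = [rec for rec, fl in flagged if getattr(fl, g) == 1]
        n = len(members)
        cells = {}
        for iid in catalog.ids:
            count = sum(m.indicators[iid] for m in members)
            cells[iid] = HeatmapCell(count=count, percent=(100.0 * count / n if n else None))
        profiles.append(GroupProfile(label=g, n=n, cells=cells))
    return profiles


def prepare_scatter(
    records: Sequence[ParticipantRecord],
    config: ThresholdConfig,
    catalog: IndicatorCatalog,
    jitter_seed: int,
) -> tuple[pd.DataFrame, ScatterRefs]:
    """Disclosure-vs-isolation scatter data with seeded jitter.

    The disclosure count is capped at ``config.scatter_cap`` for display;
    jitter is uniform on (−0.15, +0.15) on both axes from a generator seeded
    with *jitter_seed*.  Reference lines: the sample median of the capped
    disclosure count and the isolation cutoff.
    """
    if not records:
        raise ValueError("no records")
    rng = np.random.default_rng(jitter_seed)
    rows = []
    for rec in records:
        x_raw = rec.people_told
        x_capped = min(x_raw, config.scatter_cap)
        y = isolation_score(rec, catalog)
        rows.append(
            {
                "pid": rec.pid,
                "x_raw": x_raw,
                "x_capped": x_capped,
                "y": y,
                "x_jit": x_capped + rng.uniform(-0.15, 0.15),
                "y_jit": y + rng.uniform(-0.15, 0.15),
            }
        )
    df = pd.DataFrame(rows)
    refs = ScatterRefs(
        x_median=float(np.median(df["x_capped"])), y_threshold=config.isolation_min
    )
    return df, refs
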