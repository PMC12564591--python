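"""The social-exclusion indicator instrument.

The Social Isolation Index is built from 15 binary survey items covering
interpersonal rejection, identity-based exclusion, and institutional
mistreatment.  Each item belongs to one of seven thematic domains (Family,
Community, Social Support, Healthcare, Housing, Workplace, LGBT Community),
and five of the items double as the outcomes of the crisp-set QCA models
(family rejection, friend rejection, name-calling, unfair treatment at work,
and moving because of stigma).

The published study names only a handful of the 15 item wordings, so the
default catalog shipped here is a documented stand-in: it contains every
named item and fills the seven domains with plausibly worded companions.
Users holding the real instrument can substitute their own catalog from a
YAML file via :func:`IndicatorCatalog.from_yaml`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: The seven thematic domains of the instrument.
DOMAINS = (
    "Family",
    "Community",
    "Social Support",
    "Healthcare",
    "Housing",
    "Workplace",
    "LGBT Community",
)

#: The five indicators used as QCA outcomes, in canonical order.
OUTCOME_IDS = (
    "family_rejects",
    "friends_reject",
    "called_names",
    "work_unfair",
    "moved_stigma",
)


class CatalogError(ValueError):
    """Raised when an indicator catalog violates the instrument invariants."""


@dataclass(frozen=True)
class IndicatorItem:
    """One binary exclusion item: 1 = the exclusion experience is present."""

    id: str
    text: str
    domain: str
    reverse_coded: bool = False


@dataclass(frozen=True)
class IndicatorCatalog:
    """An ordered 15-item instrument with domain and reverse-coding metadata."""

    items: tuple[IndicatorItem, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 15:
            raise CatalogError(f"catalog must have exactly 15 items, got {len(self.items)}")
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            raise CatalogError("catalog item ids must be unique")
        bad = [it.domain for it in self.items if it.domain not in DOMAINS]
        if bad:
            raise CatalogError(f"unknown domain labels: {sorted(set(bad))}")
        covered = {it.domain for it in self.items}
        missing = [d for d in DOMAINS if d not in covered]
        if missing:
            raise CatalogError(f"domains without any item: {missing}")
        absent = [o for o in OUTCOME_IDS if o not in ids]
        if absent:
            raise CatalogError(f"catalog is missing QCA outcome items: {absent}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(it.id for it in self.items)

    @property
    def outcome_ids(self) -> tuple[str, ...]:
        return OUTCOME_IDS

    @property
    def non_outcome_ids(self) -> tuple[str, ...]:
        return tuple(i for i in self.ids if i not in OUTCOME_IDS)

    def domain_items(self, domain: str) -> tuple[str, ...]:
        """Item ids belonging to *domain*, in catalog order."""
        if domain not in DOMAINS:
            raise CatalogError(f"unknown domain: {domain!r}")
        return tuple(it.id for it in self.items if it.domain == domain)

    def __iter__(self):
        return iter(self.items)

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self.ids

    # ---- serialisation -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "items": [
                {
                    "id": it.id,
                    "text": it.text,
                    "domain": it.domain,
                    "reverse_coded": it.reverse_coded,
                }
                for it in self.items
            ]
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "IndicatorCatalog":
        payload = yaml.safe_load(Path(path).read_text())
        try:
            items = tuple(
                IndicatorItem(
                    id=entry["id"],
                    text=entry.get("text", entry["id"]),
                    domain=entry["domain"],
                    reverse_coded=bool(entry.get("reverse_coded", False)),
                )
                for entry in payload["items"]
            )
        except (KeyError, TypeError) as exc:
            raise CatalogError(f"malformed catalog file {path}: {exc}") from exc
        return cls(items)


def default_catalog() -> IndicatorCatalog:
    """The default 15-item stand-in instrument.

    The "I feel part of the LGBT community" item is stored already
    reverse-coded as a burden indicator (``not_part_lgbt``: 1 = exclusion),
    so every stored indicator value reads 1 = burden present.
    """
    mk = IndicatorItem
    return IndicatorCatalog(
        items=(
            mk("family_rejects", "My family rejected me after learning my HIV status", "Family"),
            mk("family_distant", "Family members have become distant from me", "Family"),
            mk("called_names", "I have been called names because of my HIV status", "Community"),
            mk("moved_stigma", "I moved residence because of HIV-related stigma", "Community"),
            mk("community_excluded", "I feel excluded from my local community", "Community"),
            mk("no_one_to_turn_to", "I feel like I have no one to turn to", "Social Support"),
            mk("friends_reject", "Friends rejected me after learning my HIV status", "Social Support"),
            mk("friends_distant", "Friends are distant after revealing my HIV status", "Social Support"),
            mk("partner_rejects", "A partner rejected me because of my HIV status", "Social Support"),
            mk("unfair_healthcare", "I am treated unfairly by healthcare providers", "Healthcare"),
            mk("housing_trouble", "I have had trouble finding or keeping housing", "Housing"),
            mk("work_unfair", "I am treated unfairly at work", "Workplace"),
            mk("work_excluded", "I am excluded by coworkers", "Workplace"),
            mk(
                "not_part_lgbt",
                "I feel part of the LGBT community (reverse-coded: 1 = does not feel part)",
                "LGBT Community",
                reverse_coded=True,
            ),
            mk("lgbt_excluded", "I feel excluded within LGBT spaces", "LGBT Community"),
        )
    )
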