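"""Random synthetic surveys with the statistical structure the pipeline assumes.

:func:`generate_random` draws independent participants from configurable
distributions: a disclosure-count distribution, a partner-disclosure
probability conditional on high disclosure, identity and race category
probabilities, and Bernoulli prevalences per exclusion indicator (optionally
overridden within subgroups defined by a raw-field flag).

The defaults mirror the composition of the 17-respondent pilot world: a
59% high-disclosure share, partner disclosure almost universal among high
disclosers and absent among low disclosers, identity split 11/2/4 and race
split 13/3/1 (as fractions), and outcome-indicator prevalences at the pilot
sample's overall rates, with the unnamed indicators at a flat 0.4.
Independence across participants and across indicators is a deliberate
simplification — real exclusion items are correlated — so these datasets
exercise the tally/oracle machinery, not substantive conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .catalog import IndicatorCatalog, default_catalog
from .records import IDENTITY_VALUES, RACE_VALUES, ParticipantRecord, ValidationError

#: Flags usable for subgroup prevalence overrides (raw-field flags only;
#: indicator-derived flags such as `isolated` would be circular).
SUBGROUP_FLAGS = (
    "told3plus",
    "informed_sex_partners",
    "lgb",
    "straight",
    "gay_or_lesbian",
    "black",
    "white",
)


def _default_people_told_probs() -> dict[int, float]:
    low, high = 7 / 17, 10 / 17
    probs = {k: low / 3 for k in (0, 1, 2)}
    probs.update({k: high / 8 for k in range(3, 11)})
    return probs


def _default_prevalence() -> dict[str, float]:
    base = {iid: 0.4 for iid in default_catalog().ids}
    base.update(
        {
            "family_rejects": 8 / 17,
            "friends_reject": 8 / 17,
            "called_names": 11 / 17,
            "work_unfair": 7 / 17,
            "moved_stigma": 7 / 17,
        }
    )
    return base


@dataclass
class SyntheticParams:
    """Distributional parameters for :func:`generate_random`."""

    n: int = 50
    people_told_probs: dict[int, float] = field(default_factory=_default_people_told_probs)
    partner_prob_given_high: float = 0.9
    partner_prob_given_low: float = 0.0
    identity_probs: dict[str, float] = field(
        default_factory=lambda: {"gay_lesbian": 11 / 17, "bisexual": 2 / 17, "straight": 4 / 17}
    )
    race_probs: dict[str, float] = field(
        default_factory=lambda: {"black": 13 / 17, "white": 3 / 17, "other": 1 / 17}
    )
    indicator_prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    #: indicator id -> {flag name: prevalence used when the flag is 1}
    subgroup_prevalence: dict[str, dict[str, float]] = field(default_factory=dict)
    #: disclosure-count threshold defining "high disclosure" for the
    #: conditional partner probability (matches the default analysis cutoff)
    disclosure_min: int = 3
    seed: int = 0

    def validate(self, catalog: IndicatorCatalog) -> None:
        if self.n < 0:
            raise ValidationError("n must be >= 0")
        for label, probs in (
            ("people_told_probs", self.people_told_probs),
            ("identity_probs", self.identity_probs),
            ("race_probs", self.race_probs),
        ):
            vals = list(probs.values())
            if any(not 0 <= p <= 1 for p in vals):
                raise ValidationError(f"{label}: probabilities must be in [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValidationError(f"{label}: probabilities must sum to 1")
        if set(self.identity_probs) != set(IDENTITY_VALUES):
            raise ValidationError(f"identity_probs keys must be {IDENTITY_VALUES}")
        if set(self.race_probs) != set(RACE_VALUES):
            raise ValidationError(f"race_probs keys must be {RACE_VALUES}")
        for p in (self.partner_prob_given_high, self.partner_prob_given_low):
            if not 0 <= p <= 1:
                raise ValidationError("partner probabilities must be in [0, 1]")
        if set(self.indicator_prevalence) != set(catalog.ids):
            raise ValidationError("indicator_prevalence must cover exactly the catalog ids")
        if any(not 0 <= p <= 1 for p in self.indicator_prevalence.values()):
            raise ValidationError("indicator prevalences must be in [0, 1]")
        for iid, overrides in self.subgroup_prevalence.items():
            if iid not in catalog.ids:
                raise ValidationError(f"subgroup_prevalence: unknown indicator {iid!r}")
            for flag, p in overrides.items():
                if flag not in SUBGROUP_FLAGS:
                    raise ValidationError(
                        f"subgroup_prevalence: flag {flag!r} not in {SUBGROUP_FLAGS}"
                    )
                if not 0 <= p <= 1:
                    raise ValidationError("subgroup prevalences must be in [0, 1]")


def _raw_flag(people_told: int, informed: int, identity: str, race: str, name: str, disclosure_min: int) -> int:
    return {
        "told3plus": int(people_told >= disclosure_min),
        "informed_sex_partners": informed,
        "lgb": int(identity in ("gay_lesbian", "bisexual")),
        "straight": int(identity == "straight"),
        "gay_or_lesbian": int(identity == "gay_lesbian"),
        "black": int(race == "black"),
        "white": int(race == "white"),
    }[name]


def generate_random(
    params: SyntheticParams, catalog: IndicatorCatalog | None = None
) -> list[ParticipantRecord]:
    """Draw ``params.n`` independent participants; reproducible per seed."""
    catalog = catalog or default_catalog()
    params.validate(catalog)
    rng = np.random.default_rng(params.seed)

    told_support = sorted(params.people_told_probs)
    told_p = np.array([params.people_told_probs[k] for k in told_support], dtype=float)
    told_p = told_p / told_p.sum()
    ident_support = list(params.identity_probs)
    ident_p = np.array([params.identity_probs[k] for k in ident_support])
    race_support = list(params.race_probs)
    race_p = np.array([params.race_probs[k] for k in race_support])

    records: list[ParticipantRecord] = []
    for i in range(params.n):
        people_told = int(told_support[int(rng.choice(len(told_support), p=told_p))])
        high = people_told >= params.disclosure_min
        p_partner = params.partner_prob_given_high if high else params.partner_prob_given_low
        informed = int(rng.random() < p_partner)
        identity = ident_support[int(rng.choice(len(ident_support), p=ident_p))]
        race = race_support[int(rng.choice(len(race_support), p=race_p))]
        indicators = {}
        for iid in catalog.ids:
            p = params.indicator_prevalence[iid]
            for flag, override in params.subgroup_prevalence.get(iid, {}).items():
                if _raw_flag(people_told, informed, identity, race, flag, params.disclosure_min):
                    p = override
            indicators[iid] = int(rng.random() < p)
        records.append(
            ParticipantRecord(
                pid=f"S{i + 1:04d}",
                people_told=people_told,
                informed_sex_partners=informed,
                sexual_identity=identity,
                race=race,
                indicators=indicators,
            )
        )
    return records
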