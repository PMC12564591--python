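"""Shared fixtures and independent brute-force oracles.

The oracle helpers below recompute flags, scores, and tallies with plain
loops over the raw record fields, deliberately bypassing the package's
pipeline (and its ledger module), so that pipeline results can be checked
against a second, independent route on data the pipeline was never tuned
to.
"""

from __future__ import annotations

import pytest

from hivburden import (
    ParticipantRecord,
    SyntheticParams,
    ThresholdConfig,
    build_fixture,
    compile_ledger,
    default_catalog,
    generate_random,
)

# ---------------------------------------------------------------------------
# Oracles (raw loops; no pipeline calls).


def oracle_score(rec: ParticipantRecord) -> int:
    return sum(rec.indicators.values())


def oracle_flag(rec: ParticipantRecord, name: str, config: ThresholdConfig) -> int:
    table = {
        "told3plus": rec.people_told >= config.disclosure_min,
        "informed_sex_partners": rec.informed_sex_partners == 1,
        "lgb": rec.sexual_identity in ("gay_lesbian", "bisexual"),
        "straight": rec.sexual_identity == "straight",
        "gay_or_lesbian": rec.sexual_identity == "gay_lesbian",
        "black": rec.race == "black",
        "white": rec.race == "white",
        "isolated": oracle_score(rec) >= config.isolation_min,
    }
    return int(table[name])


def oracle_configuration(rec, names, config) -> tuple[int, ...]:
    return tuple(oracle_flag(rec, n, config) for n in names)


def oracle_quadrant(rec, config) -> str:
    t = oracle_flag(rec, "told3plus", config)
    iso = oracle_flag(rec, "isolated", config)
    return {
        (1, 0): "adaptive_disclosure",
        (1, 1): "high_exposure",
        (0, 0): "concealed_resilient",
        (0, 1): "hidden_vulnerability",
    }[(t, iso)]


def oracle_disclosure_group(rec, config) -> str:
    t = oracle_flag(rec, "told3plus", config)
    i = rec.informed_sex_partners
    return {
        (1, 1): "high_partner",
        (1, 0): "high_nopartner",
        (0, 1): "low_partner",
        (0, 0): "low_nopartner",
    }[(t, i)]


# ---------------------------------------------------------------------------
# Fixtures.


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def config():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def ledger():
    return compile_ledger()


@pytest.fixture(scope="session")
def pilot(ledger, catalog):
    """The constraint-solved 17-record pilot fixture."""
    return build_fixture(ledger, catalog, seed=20260917)


@pytest.fixture(scope="session")
def random_datasets(catalog):
    """200 seeded random surveys, n between 1 and 50, for oracle checks."""
    datasets = []
    for seed in range(200):
        n = 1 + (seed * 7919) % 50
        datasets.append(generate_random(SyntheticParams(n=n, seed=seed), catalog))
    return datasets
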