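"""Constraint ledger, fixture solver, and the random survey generator."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from hivburden import (
    SyntheticParams,
    ValidationError,
    build_fixture,
    generate_random,
)


def test_ledger_entries_are_total_and_carry_provenance(ledger, pilot, catalog, config):
    """Every entry evaluates to a boolean on any candidate dataset and cites a source."""
    results = ledger.evaluate(pilot, catalog, config)
    assert len(results) == len(ledger)
    for r in results:
        assert isinstance(r["passed"], bool)
        assert r["provenance"]
    # also total on a dataset that obviously violates everything
    empty = ledger.evaluate([], catalog, config)
    assert all(isinstance(r["passed"], bool) for r in empty)
    assert not empty[0]["passed"]  # n_total


def test_ledger_contains_the_headline_marginals(ledger):
    assert ledger["n_total"].target == 17
    assert ledger["isolated_count"].target == 10
    assert ledger["identity_cfg_1101_count"].target == 2
    assert ledger["burden_sum_high_partner"].target == 84


def test_fixture_satisfies_every_ledger_entry(ledger, pilot, catalog, config):
    """The backbone check: each constraint asserted one by one."""
    for result in ledger.evaluate(pilot, catalog, config):
        assert result["passed"], (
            f"{result['id']}: expected {result['target']}, got {result['actual']} "
            f"({result['provenance']})"
        )


def test_fixture_is_deterministic_per_seed(ledger, catalog):
    a = build_fixture(ledger, catalog, seed=5)
    b = build_fixture(ledger, catalog, seed=5)
    assert a == b
    c = build_fixture(ledger, catalog, seed=6)
    assert not ledger.violations(c, catalog)


def test_every_single_bit_flip_violates_a_constraint(ledger, pilot, catalog, config):
    """Perturbation scan: flipping any indicator bit breaks at least one entry.

    Each participant belongs to a disclosure group with an integer burden-sum
    constraint, so any flip shifts that sum; outcome-bit flips additionally
    break configuration tallies.  The scan reports which constraints each
    flip violates.
    """
    report = {}
    for rec in pilot:
        for iid in catalog.ids:
            mutated = [
                dataclasses.replace(
                    r, indicators={**r.indicators, iid: 1 - r.indicators[iid]}
                )
                if r.pid == rec.pid
                else r
                for r in pilot
            ]
            violated = ledger.violations(mutated, catalog, config)
            report[(rec.pid, iid)] = violated
            assert violated, f"flipping {iid} of {rec.pid} violated nothing"
    # outcome flips must disturb a truth-table cell, not just the sums
    assert any(
        any(v.startswith(("identity_cfg", "race_cfg")) for v in viols)
        for (pid, iid), viols in report.items()
        if iid == "called_names"
    )


def test_generate_random_basics(catalog):
    assert generate_random(SyntheticParams(n=0, seed=1), catalog) == []
    a = generate_random(SyntheticParams(n=40, seed=9), catalog)
    b = generate_random(SyntheticParams(n=40, seed=9), catalog)
    assert a == b
    for rec in a:
        rec.validate(catalog)


def test_generate_random_rejects_invalid_probabilities(catalog):
    params = SyntheticParams(n=5)
    params.identity_probs = {"gay_lesbian": 0.9, "bisexual": 0.9, "straight": -0.8}
    with pytest.raises(ValidationError):
        generate_random(params, catalog)
    params2 = SyntheticParams(n=5)
    params2.indicator_prevalence["called_names"] = 1.7
    with pytest.raises(ValidationError):
        generate_random(params2, catalog)


def test_prevalence_recovery_within_99pct_binomial_interval(catalog):
    """Empirical indicator prevalence at n=2000 falls in the 99% CI of p."""
    n = 2000
    params = SyntheticParams(n=n, seed=123)
    params.indicator_prevalence = {iid: 0.4 for iid in catalog.ids}
    records = generate_random(params, catalog)
    lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.4)
    for iid in catalog.ids:
        count = sum(r.indicators[iid] for r in records)
        assert lo <= count <= hi, f"{iid}: {count} outside [{lo}, {hi}]"


def test_subgroup_prevalence_override(catalog):
    params = SyntheticParams(n=2000, seed=77)
    params.indicator_prevalence = {iid: 0.1 for iid in catalog.ids}
    params.subgroup_prevalence = {"called_names": {"black": 0.8}}
    records = generate_random(params, catalog)
    black = [r for r in records if r.race == "black"]
    others = [r for r in records if r.race != "black"]
    p_black = np.mean([r.indicators["called_names"] for r in black])
    p_other = np.mean([r.indicators["called_names"] for r in others])
    assert p_black > 0.7
    assert p_other < 0.2
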