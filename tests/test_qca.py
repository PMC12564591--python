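"""Truth-table construction, consistency, coverage, consistent-set scans."""

from collections import Counter

import pytest

from hivburden import (
    OUTCOME_IDS,
    ConditionSet,
    ParticipantRecord,
    build_truth_table,
    consistency,
    coverage,
    identify_consistent,
)
from tests.conftest import oracle_configuration

IDENTITY_CONDITIONS = ConditionSet(("told3plus", "informed_sex_partners", "lgb", "straight"))


def test_condition_set_validation():
    with pytest.raises(ValueError):
        ConditionSet(("told3plus",))  # too few
    with pytest.raises(ValueError):
        ConditionSet(("told3plus",) * 3)  # duplicates
    with pytest.raises(ValueError):
        ConditionSet(("told3plus", "nope"))  # unknown flag


def test_single_record_table(catalog, config):
    rec = ParticipantRecord(
        pid="X", people_told=5, informed_sex_partners=1,
        sexual_identity="gay_lesbian", race="black",
        indicators=dict(zip(catalog.ids, [1] + [0] * 14)),
    )
    table = build_truth_table([rec], config, catalog, IDENTITY_CONDITIONS, OUTCOME_IDS)
    assert len(table.rows) == 1
    row = table.rows[0]
    assert row.configuration == (1, 1, 1, 0)
    assert row.count == 1
    assert {t.percent for t in row.outcomes.values()} <= {0.0, 100.0}


def test_rows_sorted_lexicographically_and_partition_n(random_datasets, catalog, config):
    for records in random_datasets:
        table = build_truth_table(records, config, catalog, IDENTITY_CONDITIONS, OUTCOME_IDS)
        cfgs = [r.configuration for r in table.rows]
        assert cfgs == sorted(cfgs)
        assert len(set(cfgs)) == len(cfgs)
        assert sum(r.count for r in table.rows) == len(records)  # min_freq=1


def test_min_freq_drops_rare_configurations(pilot, catalog, config):
    full = build_truth_table(pilot, config, catalog, IDENTITY_CONDITIONS, OUTCOME_IDS)
    filtered = build_truth_table(
        pilot, config, catalog, IDENTITY_CONDITIONS, OUTCOME_IDS, min_freq=2
    )
    kept = {r.configuration for r in filtered.rows}
    assert kept == {r.configuration for r in full.rows if r.count >= 2}


def test_unknown_outcome_rejected(pilot, catalog, config):
    with pytest.raises(ValueError):
        build_truth_table(pilot, config, catalog, IDENTITY_CONDITIONS, ["no_such_item"])


def test_tallies_and_consistency_match_oracle(random_datasets, catalog, config):
    for records in random_datasets:
        table = build_truth_table(records, config, catalog, IDENTITY_CONDITIONS, OUTCOME_IDS)
        expected_counts = Counter(
            oracle_configuration(r, IDENTITY_CONDITIONS.names, config) for r in records
        )
        assert {r.configuration: r.count for r in table.rows} == dict(expected_counts)
        for row in table.rows:
            members = [
                r for r in records
                if oracle_configuration(r, IDENTITY_CONDITIONS.names, config)
                == row.configuration
            ]
            for oid in OUTCOME_IDS:
                expected = sum(m.indicators[oid] for m in members)
                assert row.outcomes[oid].count == expected
                assert consistency(row, oid) == pytest.approx(expected / len(members))
                assert 0.0 <= consistency(row, oid) <= 1.0


def test_coverage_matches_oracle_and_partitions(random_datasets, catalog, config):
    checked = 0
    for records in random_datasets:
        if not any(r.indicators["called_names"] for r in records):
            continue
        table = build_truth_table(records, config, catalog, IDENTITY_CONDITIONS, OUTCOME_IDS)
        total = sum(r.indicators["called_names"] for r in records)
        acc = 0.0
        for row in table.rows:
            cov = coverage(table, row.configuration, "called_names", records)
            joint = sum(
                r.indicators["called_names"] for r in records
                if oracle_configuration(r, IDENTITY_CONDITIONS.names, config)
                == row.configuration
            )
            assert cov == pytest.approx(joint / total)
            acc += cov
        # observed configurations partition the cases, so coverages sum to 1
        assert acc == pytest.approx(1.0)
        checked += 1
        if checked >= 40:
            break
    assert checked >= 10


def test_coverage_undefined_when_outcome_absent(catalog, config):
    rec = ParticipantRecord(
        pid="X", people_told=0, informed_sex_partners=0,
        sexual_identity="straight", race="other",
        indicators=dict.fromkeys(catalog.ids, 0),
    )
    table = build_truth_table([rec], config, catalog, IDENTITY_CONDITIONS, OUTCOME_IDS)
    with pytest.raises(ValueError):
        coverage(table, (0, 0, 0, 1), "called_names", [rec])


def test_identify_consistent_matches_brute_scan(random_datasets, catalog, config):
    for records in random_datasets[:60]:
        table = build_truth_table(records, config, catalog, IDENTITY_CONDITIONS, OUTCOME_IDS)
        for threshold in (0.5, 1.0):
            hits = identify_consistent(table, "family_rejects", threshold)
            expected = [
                r.configuration for r in table.rows
                if r.outcomes["family_rejects"].count / r.count >= threshold
            ]
            assert [r.configuration for r in hits] == expected
    with pytest.raises(ValueError):
        identify_consistent(table, "family_rejects", 0.0)


def test_tiny_threshold_returns_every_row_with_a_case(pilot, catalog, config):
    table = build_truth_table(pilot, config, catalog, IDENTITY_CONDITIONS, OUTCOME_IDS)
    hits = identify_consistent(table, "called_names", 1e-9)
    expected = [r.configuration for r in table.rows if r.outcomes["called_names"].count > 0]
    assert [r.configuration for r in hits] == expected


def test_complementary_conditions_never_both_one(random_datasets, catalog, config):
    for records in random_datasets[:60]:
        table = build_truth_table(records, config, catalog, IDENTITY_CONDITIONS, OUTCOME_IDS)
        for row in table.rows:
            lgb, straight = row.configuration[2], row.configuration[3]
            assert not (lgb == 1 and straight == 1)


def test_truth_table_is_order_invariant(pilot, catalog, config):
    table = build_truth_table(pilot, config, catalog, IDENTITY_CONDITIONS, OUTCOME_IDS)
    permuted = list(reversed(pilot))
    table2 = build_truth_table(permuted, config, catalog, IDENTITY_CONDITIONS, OUTCOME_IDS)
    assert [(r.configuration, r.count, r.outcomes) for r in table.rows] == [
        (r.configuration, r.count, r.outcomes) for r in table2.rows
    ]
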