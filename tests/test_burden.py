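"""Burden means, domain profiles, heatmap tallies, scatter preparation."""

import numpy as np
import pytest

from hivburden import (
    DISCLOSURE_GROUPS,
    DOMAINS,
    ParticipantRecord,
    domain_profile,
    group_mean_burden,
    indicator_heatmap,
    prepare_scatter,
)
from tests.conftest import oracle_disclosure_group, oracle_flag, oracle_score


def test_group_means_match_oracle_on_random_data(random_datasets, catalog, config):
    for records in random_datasets:
        result = group_mean_burden(records, config, catalog)
        for g in DISCLOSURE_GROUPS:
            members = [r for r in records if oracle_disclosure_group(r, config) == g]
            assert result[g].n == len(members)
            if members:
                expected = sum(oracle_score(r) for r in members) / len(members)
                assert result[g].mean == pytest.approx(expected)
            else:
                assert result[g].mean is None


def test_group_means_weighted_by_n_recover_overall_mean(random_datasets, catalog, config):
    for records in random_datasets[:50]:
        result = group_mean_burden(records, config, catalog)
        weighted = sum(b.n * b.mean for b in result.values() if b.mean is not None)
        assert weighted == pytest.approx(sum(oracle_score(r) for r in records))


def test_single_member_group_mean_is_its_score(catalog, config):
    rec = ParticipantRecord(
        pid="X", people_told=5, informed_sex_partners=0,
        sexual_identity="straight", race="other",
        indicators=dict(zip(catalog.ids, [1, 1, 1] + [0] * 12)),
    )
    result = group_mean_burden([rec], config, catalog)
    assert result["high_nopartner"] .n == 1
    assert result["high_nopartner"].mean == 3.0


@pytest.mark.parametrize("fill,expected", [(0, 0.0), (1, 1.0)])
def test_domain_profile_extremes(fill, expected, catalog, config):
    recs = [
        ParticipantRecord(
            pid=f"X{i}", people_told=5, informed_sex_partners=1,
            sexual_identity="gay_lesbian", race="black",
            indicators=dict.fromkeys(catalog.ids, fill),
        )
        for i in range(3)
    ]
    prof = domain_profile(recs, "high_partner", config, catalog)
    assert prof.n == 3
    assert all(v == expected for v in prof.values.values())


def test_domain_profile_matches_double_mean_oracle(random_datasets, catalog, config):
    checked = 0
    for records in random_datasets:
        members = [r for r in records
                   if oracle_disclosure_group(r, config) == "low_nopartner"]
        if not members:
            continue
        prof = domain_profile(records, "low_nopartner", config, catalog)
        assert prof.n == len(members)
        for d in DOMAINS:
            items = [it.id for it in catalog if it.domain == d]
            expected = np.mean(
                [sum(m.indicators[i] for i in items) / len(items) for m in members]
            )
            assert prof.values[d] == pytest.approx(expected)
            assert 0.0 <= prof.values[d] <= 1.0
        checked += 1
        if checked >= 30:
            break
    assert checked >= 10


def test_domain_profile_empty_group_raises(catalog, config, pilot):
    with pytest.raises(ValueError):
        domain_profile(pilot, "low_partner", config, catalog)


def test_heatmap_counts_match_oracle(random_datasets, catalog, config):
    group_defs = ("told3plus", "informed_sex_partners", "gay_or_lesbian",
                  "straight", "black", "white")
    for records in random_datasets[:60]:
        profiles = indicator_heatmap(records, config, catalog, group_defs)
        for prof in profiles:
            members = [r for r in records if oracle_flag(r, prof.label, config) == 1]
            assert prof.n == len(members)
            for iid in catalog.ids:
                expected = sum(m.indicators[iid] for m in members)
                assert prof.cells[iid].count == expected
                if members:
                    assert prof.cells[iid].percent == pytest.approx(
                        100 * expected / len(members)
                    )
                else:
                    assert prof.cells[iid].percent is None


def test_heatmap_rejects_unknown_group(catalog, config, pilot):
    with pytest.raises(ValueError):
        indicator_heatmap(pilot, config, catalog, ["not_a_flag"])


def test_scatter_cap_and_determinism(pilot, catalog, config):
    df1, refs1 = prepare_scatter(pilot, config, catalog, jitter_seed=11)
    df2, refs2 = prepare_scatter(pilot, config, catalog, jitter_seed=11)
    assert df1.equals(df2)
    assert refs1 == refs2
    assert (df1["x_capped"] <= config.scatter_cap).all()
    assert refs1.y_threshold == config.isolation_min


def test_scatter_caps_large_counts(catalog, config):
    rec = ParticipantRecord(
        pid="X", people_told=25, informed_sex_partners=1,
        sexual_identity="straight", race="white",
        indicators=dict.fromkeys(catalog.ids, 0),
    )
    df, _ = prepare_scatter([rec], config, catalog, jitter_seed=0)
    assert df.loc[0, "x_raw"] == 25
    assert df.loc[0, "x_capped"] == 10


def test_jitter_stays_within_bounds(random_datasets, catalog, config):
    for seed, records in enumerate(random_datasets[:20]):
        df, _ = prepare_scatter(records, config, catalog, jitter_seed=seed)
        assert (abs(df["x_jit"] - df["x_capped"]) <= 0.15).all()
        assert (abs(df["y_jit"] - df["y"]) <= 0.15).all()
        assert (df["y"] == [oracle_score(r) for r in records]).all()
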