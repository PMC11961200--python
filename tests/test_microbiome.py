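"""Abundance-table preprocessing and cohort-level network summaries."""

import numpy as np
import pandas as pd
import pytest

from edame import (
    CohortNetworkSet,
    SignedNetwork,
    aggregate_to_phylum,
    binarize_to_attractors,
    quality_index,
    read_abundance_table,
    spearman_network,
    summary_network,
    write_abundance_table,
)


@pytest.fixture
def species_table():
    return pd.DataFrame(
        {
            "s1": [0.1, 0.2, 0.3, 0.0],
            "s2": [0.0, 0.0, 0.5, 0.5],
            "s3": [0.4, 0.1, 0.0, 0.5],
        },
        index=["sp_a", "sp_b", "sp_c", "sp_d"],
    )


TAXONOMY = {"sp_a": "Firmicutes", "sp_b": "Firmicutes",
            "sp_c": "Bacteroidetes", "sp_d": "Actinobacteria"}


class TestAggregateToPhylum:
    def test_same_phylum_rows_are_summed(self, species_table):
        agg = aggregate_to_phylum(species_table, TAXONOMY)
        assert agg.loc["Firmicutes", "s1"] == pytest.approx(0.3)
        assert agg.shape == (3, 3)

    def test_column_sums_preserved(self, species_table):
        agg = aggregate_to_phylum(species_table, TAXONOMY)
        assert np.allclose(agg.sum(), species_table.sum())

    def test_identity_map_on_phylum_table_is_noop(self, species_table):
        agg = aggregate_to_phylum(species_table, TAXONOMY)
        again = aggregate_to_phylum(agg, {p: p for p in agg.index})
        pd.testing.assert_frame_equal(agg.sort_index(), again.sort_index())

    def test_unmapped_taxon_is_reported(self, species_table):
        with pytest.raises(KeyError, match="sp_d"):
            aggregate_to_phylum(
                species_table, {k: v for k, v in TAXONOMY.items() if k != "sp_d"}
            )


class TestBinarize:
    def test_zero_threshold_is_presence_absence(self, species_table):
        attrs, taxa = binarize_to_attractors(species_table, threshold=0.0)
        assert taxa == list(species_table.index)
        # s1 -> (1,1,1,0), s2 -> (0,0,1,1), s3 -> (1,1,0,1): all distinct
        assert len(attrs.all_states) == 3
        assert 0b0111 in attrs.all_states

    def test_duplicate_samples_collapse(self):
        tab = pd.DataFrame(
            {"a": [1.0, 0.0], "b": [1.0, 0.0], "c": [0.0, 2.0], "d": [1.0, 1.0]},
            index=["t1", "t2"],
        )
        attrs, _ = binarize_to_attractors(tab)
        assert len(attrs.all_states) == 3  # a == b

    def test_monotone_in_threshold(self, species_table):
        lo, _ = binarize_to_attractors(species_table, threshold=0.0)
        hi, _ = binarize_to_attractors(species_table, threshold=0.25)
        # raising the threshold can only clear bits in each sample pattern
        n = len(species_table.index)
        lo_pats = sorted(lo.all_states)
        for s_hi in hi.all_states:
            assert any((s_hi & s_lo) == s_hi for s_lo in lo_pats)

    def test_drop_empty_removes_zero_state(self):
        tab = pd.DataFrame({"a": [0.0, 0.0], "b": [1.0, 0.0]}, index=["x", "y"])
        keep, _ = binarize_to_attractors(tab)
        drop, _ = binarize_to_attractors(tab, drop_empty=True)
        assert 0 in keep.all_states
        assert 0 not in drop.all_states


def _net(n, *edges):
    return SignedNetwork(n, frozenset(edges))


class TestSummaryNetwork:
    def test_single_study_unit_weight(self):
        net = _net(4, (0, 1, 1), (1, 2, -1))
        summ = summary_network(CohortNetworkSet("h", ((net, 1.0),)))
        got = {(r.i, r.j): r.weight for r in summ.itertuples()}
        assert got == {(0, 1): 1.0, (1, 2): -1.0}

    def test_opposite_signs_cancel(self):
        a = _net(3, (0, 1, 1))
        b = _net(3, (0, 1, -1))
        summ = summary_network(CohortNetworkSet("h", ((a, 0.7), (b, 0.7))))
        assert len(summ) == 0

    def test_four_agreeing_studies_sum_ji_weights(self):
        nets = tuple((_net(3, (0, 1, 1)), ji) for ji in (0.9, 0.8, 0.7, 0.6))
        summ = summary_network(CohortNetworkSet("h", nets))
        assert summ.iloc[0].weight == pytest.approx(3.0)

    def test_mismatched_node_sets_raise(self):
        with pytest.raises(ValueError):
            summary_network(
                CohortNetworkSet("h", ((_net(3, (0, 1, 1)), 1.0),
                                       (_net(4, (0, 1, 1)), 1.0)))
            )


class TestQualityIndex:
    def test_all_identical_networks_give_unit_qi(self):
        net = _net(4, (0, 1, 1), (2, 3, -1))
        cohorts = [
            CohortNetworkSet("a", ((net, 1.0), (net, 1.0))),
            CohortNetworkSet("b", ((net, 1.0), (net, 1.0))),
        ]
        assert quality_index(cohorts) == pytest.approx(1.0)

    def test_disjoint_cohorts_flagged_infinite(self):
        a = _net(4, (0, 1, 1))
        b = _net(4, (2, 3, -1))
        cohorts = [
            CohortNetworkSet("a", ((a, 1.0), (a, 1.0))),
            CohortNetworkSet("b", ((b, 1.0), (b, 1.0))),
        ]
        with pytest.warns(UserWarning):
            assert quality_index(cohorts) == float("inf")

    def test_matches_hand_computed_ratio(self):
        # cohort A: two identical nets (within JI 1); cohort B: two nets
        # overlapping 1/3; across pairs: each A-net vs each B-net
        a = _net(4, (0, 1, 1), (1, 2, -1))
        b1 = _net(4, (0, 1, 1), (2, 3, 1))
        b2 = _net(4, (0, 1, 1), (1, 3, -1))
        cohorts = [
            CohortNetworkSet("A", ((a, 1.0), (a, 1.0))),
            CohortNetworkSet("B", ((b1, 1.0), (b2, 1.0))),
        ]
        within = np.mean([1.0, 1 / 3])
        across = np.mean([1 / 3, 1 / 3, 1 / 3, 1 / 3])
        assert quality_index(cohorts) == pytest.approx(within / across)

    def test_label_permutation_concentrates_near_one(self):
        # two clearly distinct cohorts: true QI >> permuted QI ~ 1
        rng = np.random.default_rng(0)
        from edame import generate_random_network, rewire_edges

        base_a = generate_random_network(8, 6, 6, seed=1)
        base_b = generate_random_network(8, 6, 6, seed=2)
        nets_a = [rewire_edges(base_a, 1, seed=s)[0] for s in range(3)]
        nets_b = [rewire_edges(base_b, 1, seed=s)[0] for s in range(3)]
        truth = quality_index([
            CohortNetworkSet("a", tuple((n, 1.0) for n in nets_a)),
            CohortNetworkSet("b", tuple((n, 1.0) for n in nets_b)),
        ])
        assert truth > 1.0
        perm_qis = []
        pool = nets_a + nets_b
        for _ in range(30):
            idx = rng.permutation(6)
            ca = CohortNetworkSet("a", tuple((pool[i], 1.0) for i in idx[:3]))
            cb = CohortNetworkSet("b", tuple((pool[i], 1.0) for i in idx[3:]))
            perm_qis.append(quality_index([ca, cb]))
        assert abs(np.median(perm_qis) - 1.0) < abs(truth - 1.0)

    def test_degenerate_cohorts_rejected(self):
        net = _net(3, (0, 1, 1))
        with pytest.raises(ValueError):
            quality_index([CohortNetworkSet("a", ((net, 1.0), (net, 1.0)))])


def test_abundance_table_roundtrip_and_validation(tmp_path, species_table):
    path = tmp_path / "abund.tsv"
    write_abundance_table(species_table, path)
    back = read_abundance_table(path)
    pd.testing.assert_frame_equal(back, species_table)
    bad = species_table.copy()
    bad.iloc[0, 0] = -1.0
    write_abundance_table(bad, path)
    with pytest.raises(ValueError):
        read_abundance_table(path)


def test_spearman_network_flags_strong_monotone_pairs():
    rng = np.random.default_rng(1)
    x = rng.random(30)
    tab = pd.DataFrame(
        [x, x + 0.01 * rng.random(30), 1 - x, rng.random(30)],
        index=["a", "b", "c", "d"],
    )
    net = spearman_network(tab, threshold=0.5)
    assert net.edge_sign(0, 1) == 1
    assert net.edge_sign(0, 2) == -1
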