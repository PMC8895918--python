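"""VJL grouping, nearest neighbors, and clonal-lineage network inference."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from clonostat.lineage import (
    build_lineages,
    degree_stats,
    group_by_vjl,
    identity_pct,
    mutated_ratio,
    nearest_neighbor,
    nn_distribution,
)

from conftest import CDR3_A, CDR3_A1, CDR3_B, make_clone_table, random_nt


def brute_force_components(df, threshold):
    """All-pairs O(n^2) reference for lineage components."""
    rows = df.groupby(["v_gene", "j_gene", "cdr3_nt"], as_index=False)["count"].sum()
    nodes = [(r.v_gene, r.j_gene, r.cdr3_nt) for r in rows.itertuples()]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b in itertools.combinations(nodes, 2):
        if a[0] == b[0] and a[1] == b[1] and len(a[2]) == len(b[2]):
            if identity_pct(a[2], b[2]) >= threshold - 1e-9:
                g.add_edge(a, b)
    return {frozenset(c) for c in nx.connected_components(g) if len(c) >= 2}


def random_subset(rng, n, n_v=3, n_j=2, lengths=(18, 21, 24), mutant_prob=0.4):
    """Random clonotypes with a planted chance of near-duplicates."""
    rows, pool = [], []
    for _ in range(n):
        if pool and rng.random() < mutant_prob:
            v, j, nt = pool[rng.integers(len(pool))]
            pos = int(rng.integers(len(nt)))
            base = "ACGT"[int(rng.integers(4))]
            nt = nt[:pos] + base + nt[pos + 1:]
        else:
            v = f"IGHV{rng.integers(n_v)}"
            j = f"IGHJ{rng.integers(n_j)}"
            nt = random_nt(rng, int(rng.choice(lengths)))
        pool.append((v, j, nt))
        rows.append((v, j, nt, "X" * (len(nt) // 3), int(rng.integers(1, 5))))
    return make_clone_table(rows)


class TestIdentity:
    def test_equal_sequences_are_100(self):
        assert identity_pct("ACGTACGT", "ACGTACGT") == 100.0

    @pytest.mark.parametrize("length,mismatches,expected", [
        (20, 1, 95.0), (36, 18, 50.0), (21, 1, 100 * 20 / 21),
    ])
    def test_hand_computed_values(self, length, mismatches, expected):
        a = "A" * length
        b = "C" * mismatches + "A" * (length - mismatches)
        assert identity_pct(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = random_nt(rng, 30), random_nt(rng, 30)
            assert identity_pct(a, b) == identity_pct(b, a)

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            identity_pct("ACGT", "ACGTA")


class TestGrouping:
    def test_same_vj_different_lengths_split(self):
        df = make_clone_table([
            ("IGHV1", "IGHJ1", "A" * 18, "X" * 6, 1),
            ("IGHV1", "IGHJ1", "A" * 21, "X" * 7, 1),
        ])
        assert len(group_by_vjl(df)) == 2

    def test_identical_cdr3_different_j_split(self):
        df = make_clone_table([
            ("IGHV1", "IGHJ1", CDR3_A, "X" * 7, 1),
            ("IGHV1", "IGHJ2", CDR3_A, "X" * 7, 1),
        ])
        assert len(group_by_vjl(df)) == 2

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(1)
        df = random_subset(rng, 80)
        groups = group_by_vjl(df)
        seen = [(g.key[0], g.key[1], s) for g in groups for s in g.seqs]
        distinct = set(zip(df.v_gene, df.j_gene, df.cdr3_nt))
        assert len(seen) == len(set(seen)) == len(distinct)

    def test_duplicate_clonotypes_collapse_with_summed_counts(self):
        df = make_clone_table([
            ("IGHV1", "IGHJ1", CDR3_A, "X" * 7, 2),
            ("IGHV1", "IGHJ1", CDR3_A, "X" * 7, 3),
        ])
        (group,) = group_by_vjl(df)
        assert group.seqs == [CDR3_A] and group.counts.tolist() == [5]


class TestNearestNeighbor:
    def test_symmetric_pair(self):
        df = make_clone_table([
            ("IGHV1", "IGHJ1", CDR3_A, "X" * 7, 1),
            ("IGHV1", "IGHJ1", CDR3_A1, "X" * 7, 1),
        ])
        (group,) = group_by_vjl(df)
        nn = nearest_neighbor(group)
        expected = identity_pct(CDR3_A, CDR3_A1)
        assert nn == {CDR3_A: expected, CDR3_A1: expected}

    def test_max_over_brute_force_all_pairs(self):
        rng = np.random.default_rng(2)
        df = random_subset(rng, 60)
        for group in group_by_vjl(df):
            nn = nearest_neighbor(group)
            for seq in group.seqs:
                if len(group) == 1:
                    assert nn == {}
                else:
                    expected = max(identity_pct(seq, other)
                                   for other in group.seqs if other != seq)
                    assert nn[seq] == pytest.approx(expected, abs=1e-9)

    def test_singleton_yields_empty_map(self):
        df = make_clone_table([("IGHV1", "IGHJ1", CDR3_A, "X" * 7, 1)])
        (group,) = group_by_vjl(df)
        assert nearest_neighbor(group) == {}


class TestNNDistribution:
    def test_planted_mutants_mass_in_high_identity_bins(self):
        rng = np.random.default_rng(3)
        ancestor = random_nt(rng, 39)
        mutants = [ancestor[:i] + ("A" if ancestor[i] != "A" else "C") + ancestor[i + 1:]
                   for i in range(5)]
        df = make_clone_table([("IGHV1", "IGHJ1", s, "X" * 13, 1)
                               for s in [ancestor] + mutants])
        dist = nn_distribution(df)
        assert (dist.identity_bin >= 95).all()
        assert dist.n_clonotypes.sum() == 6
        assert set(dist.cdr3_length) == {39}

    def test_random_sequences_mass_below_90(self):
        rng = np.random.default_rng(4)
        df = make_clone_table([("IGHV1", "IGHJ1", random_nt(rng, 30), "X" * 10, 1)
                               for _ in range(40)])
        dist = nn_distribution(df)
        assert (dist.identity_bin < 90).all()

    def test_empty_subset_yields_empty_distribution(self):
        assert nn_distribution(make_clone_table([])).empty

    def test_total_counts_clonotypes_with_companions(self):
        rng = np.random.default_rng(5)
        df = random_subset(rng, 100)
        dist = nn_distribution(df)
        groups = group_by_vjl(df)
        expected = sum(len(g) for g in groups if len(g) >= 2)
        assert dist.n_clonotypes.sum() == expected


class TestBuildLineages:
    def test_pair_at_exact_threshold_is_one_lineage(self):
        a = "A" * 20
        b = "C" + "A" * 19  # exactly 95.0%
        df = make_clone_table([("IGHV1", "IGHJ1", a, "X" * 6, 1),
                               ("IGHV1", "IGHJ1", b, "X" * 6, 1)])
        net = build_lineages(df, threshold_pct=95.0)
        assert len(net.lineages) == 1 and len(net.lineages[0]) == 2

    def test_single_linkage_chain_without_direct_edge(self):
        u = "A" * 25
        v = "C" + "A" * 24            # 96% to u
        w = "C" + "G" + "A" * 23      # 96% to v, 92% to u
        df = make_clone_table([("IGHV1", "IGHJ1", s, "X" * 8, 1) for s in (u, v, w)])
        df["cdr3_aa"] = "X" * 8  # frame not needed for clustering
        net = build_lineages(df, threshold_pct=95.0)
        assert len(net.lineages) == 1 and len(net.lineages[0]) == 3
        assert not net.graph.has_edge(("IGHV1", "IGHJ1", u), ("IGHV1", "IGHJ1", w))

    def test_isolated_clonotype_forms_no_lineage(self):
        df = make_clone_table([("IGHV1", "IGHJ1", CDR3_A, "X" * 7, 1),
                               ("IGHV2", "IGHJ1", CDR3_B, "X" * 7, 1)])
        assert build_lineages(df).lineages == []

    def test_components_match_brute_force_reference(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            df = random_subset(rng, int(rng.integers(20, 150)))
            net = build_lineages(df, threshold_pct=95.0)
            assert {frozenset(c) for c in net.lineages} == brute_force_components(df, 95.0)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        df = random_subset(rng, 200)
        nets = {t: build_lineages(df, threshold_pct=t) for t in (90.0, 95.0, 99.0)}
        edges = [nets[t].graph.number_of_edges() for t in (90.0, 95.0, 99.0)]
        in_lineage = [sum(len(c) for c in nets[t].lineages) for t in (90.0, 95.0, 99.0)]
        max_deg = [degree_stats(nets[t]).max_degree for t in (90.0, 95.0, 99.0)]
        for series in (edges, in_lineage, max_deg):
            assert series == sorted(series, reverse=True)

    def test_edges_never_cross_group_boundaries(self):
        rng = np.random.default_rng(8)
        df = random_subset(rng, 120)
        net = build_lineages(df, threshold_pct=50.0)  # permissive: many edges
        for (v1, j1, s1), (v2, j2, s2) in net.graph.edges():
            assert (v1, j1, len(s1)) == (v2, j2, len(s2))


class TestLineageStatistics:
    def _net(self, seqs, threshold=95.0):
        df = make_clone_table([("IGHV1", "IGHJ1", s, "X" * (len(s) // 3), 1)
                               for s in seqs])
        return build_lineages(df, threshold_pct=threshold)

    def test_mutated_ratio_arithmetic(self):
        a = "A" * 20
        b = "C" + "A" * 19
        others = ["C" * 10 + random_nt(np.random.default_rng(i), 10) for i in range(3)]
        net = self._net([a, b] + others, threshold=95.0)
        # guard: the random tails must not have formed extra lineages
        assert len(net.lineages) == 1
        assert mutated_ratio(net) == pytest.approx(100 * 2 / net.n_clonotypes)
        assert mutated_ratio(net, total_clonotypes=100) == pytest.approx(2.0)

    def test_no_lineages_means_zero_ratio(self):
        net = self._net([CDR3_A, CDR3_B])
        assert mutated_ratio(net) == 0.0

    def test_two_node_lineage_degree_distribution(self):
        net = self._net(["A" * 20, "C" + "A" * 19])
        stats = degree_stats(net)
        assert stats.max_degree == 1
        assert stats.ratios.loc[1] == 1.0

    def test_triangle_all_degree_two(self):
        a = "A" * 40
        b = "C" + "A" * 39
        c = "G" + "A" * 39
        net = self._net([a, b, c], threshold=95.0)
        stats = degree_stats(net)
        assert stats.max_degree == 2
        assert stats.ratios.loc[2] == 1.0

    def test_star_max_degree_equals_leaf_count(self):
        hub = "A" * 100
        leaves = [hub[:i] + "C" + hub[i + 1:] for i in range(0, 50, 10)]
        net = self._net([hub] + leaves, threshold=98.0)
        assert degree_stats(net).max_degree == len(leaves)

    def test_degree_cap_pools_high_degrees(self):
        hub = "A" * 100
        leaves = [hub[:i] + "C" + hub[i + 1:] for i in range(0, 90, 9)]
        stats = degree_stats(self._net([hub] + leaves, threshold=97.0), cap=8)
        assert stats.ratios.loc[8] > 0  # the hub's degree 10 pooled at 8
        assert stats.ratios.sum() == pytest.approx(1.0)

    def test_empty_network_statistics(self):
        net = self._net([CDR3_A])
        stats = degree_stats(net)
        assert stats.max_degree == 0 and stats.ratios.empty
        with pytest.raises(ValueError):
            mutated_ratio(net, total_clonotypes=0)
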