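"""Cohesiveness communities, maximal cliques, cross-cell dynamics, coherence."""

from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hidpet.cliques import (
    Clique,
    classify_clique_patterns,
    cohesiveness,
    compare_cliques_across_cells,
    expression_coherence,
    find_communities,
    map_clique_spans,
    maximal_cliques,
    regulated_genes,
)
from hidpet.formats import GenomicInterval, IntervalSet, Loop
from hidpet.hierarchy import HierarchyAssignment
from hidpet.loops import annotate_anchors
from hidpet.motifs import MotifOccurrence

from conftest import random_graph


def brute_force_max_cliques(g: nx.Graph):
    """Oracle: all-subsets enumeration of maximal cliques."""
    nodes = list(g.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in combinations(nodes, r):
            if all(g.has_edge(a, b) for a, b in combinations(sub, 2)):
                cliques.append(set(sub))
    return [c for c in cliques if not any(c < d for d in cliques)]


class TestCohesiveness:
    def test_triangle_with_penalty_two(self, two_triangles):
        assert cohesiveness(two_triangles.subgraph({"a", "b", "c"}), {"a", "b", "c"}) == pytest.approx(1 / 3)

    def test_isolated_triangle_penalty_zero(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert cohesiveness(g, {"a", "b", "c"}, penalty=0) == 1.0

    def test_single_node_all_boundary(self):
        g = nx.Graph([("a", "b"), ("a", "c")])
        assert cohesiveness(g, {"a"}, penalty=0) == 0.0

    def test_missing_node_rejected(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError):
            cohesiveness(g, {"z"})


class TestCommunities:
    def test_two_triangles_recovered(self, two_triangles):
        comms = find_communities(two_triangles)
        members = sorted(sorted(c.members) for c in comms)
        assert members == [["a", "b", "c"], ["d", "e", "f"]]

    def test_two_triangles_are_brute_force_optima_among_small_subsets(self, two_triangles):
        """Exhaustive check over all subsets of size <= 4: the two planted
        triangles are the cohesiveness co-optima, and both are returned."""
        nodes = list(two_triangles.nodes)
        scored = sorted(
            (
                (cohesiveness(two_triangles, s), frozenset(s))
                for r in range(1, 5)
                for s in combinations(nodes, r)
            ),
            key=lambda t: -t[0],
        )
        top = {m for f, m in scored if f == scored[0][0]}
        assert top == {frozenset("abc"), frozenset("def")}
        assert {c.members for c in find_communities(two_triangles)} == top

    def test_complete_graph_single_community(self):
        g = nx.complete_graph(5)
        comms = find_communities(g)
        assert len(comms) == 1 and comms[0].members == frozenset(range(5))

    def test_overlap_score_below_cutoff_not_merged(self):
        # omega({1,2,3},{2,3,4}) = 4/9 < 0.8: two chained triangles stay apart
        g = nx.Graph()
        g.add_edges_from([(1, 2), (2, 3), (1, 3), (3, 4), (2, 4)])
        from hidpet.cliques import _overlap_score

        assert _overlap_score(frozenset({1, 2, 3}), frozenset({2, 3, 4})) == pytest.approx(4 / 9)

    def test_local_optimality_of_returned_communities(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            g = random_graph(rng, int(rng.integers(5, 11)), 0.45)
            for c in find_communities(g, min_size=1, min_density=0.0):
                f = cohesiveness(g, c.members)
                for n in set(g.nodes) - c.members:
                    assert cohesiveness(g, c.members | {n}) <= f + 1e-12
                if len(c.members) > 1:
                    for n in c.members:
                        assert cohesiveness(g, c.members - {n}) <= f + 1e-12


class TestMaximalCliques:
    def test_k4_single_clique(self):
        g = nx.complete_graph(4)
        cliques = maximal_cliques(g)
        assert [sorted(c.members) for c in cliques] == [[0, 1, 2, 3]]

    def test_five_cycle_filtered_empty(self):
        g = nx.cycle_graph(5)
        # oracle: maximal cliques of C5 are its 5 edges, all below min size
        assert maximal_cliques(g) == []
        assert sorted(map(len, brute_force_max_cliques(g))) == [2] * 5

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            g = random_graph(rng, int(rng.integers(4, 13)), float(rng.uniform(0.2, 0.8)))
            got = {frozenset(c.members) for c in maximal_cliques(g, 1, 13)}
            expected = {frozenset(c) for c in brute_force_max_cliques(g)}
            assert got == expected

    def test_size_bounds_applied(self):
        g = nx.complete_graph(12)
        assert maximal_cliques(g, 3, 10) == []  # the single K12 clique exceeds 10


class TestSpansAndVenn:
    HIER = HierarchyAssignment(
        {"a": 2, "b": 2, "c": 2, "d": 1, "e": 3, "f": 5}, 5, 0.0, 0.0, {}
    )

    def test_single_level_clique(self):
        df = map_clique_spans([Clique(frozenset("abc"))], self.HIER, [])
        assert df.loc[0, "levels_spanned"] == 1

    def test_multi_level_clique(self):
        df = map_clique_spans([Clique(frozenset("def"))], self.HIER, [])
        assert df.loc[0, "levels_spanned"] == 3

    def test_communities_touched_union_count(self):
        from hidpet.cliques import Community

        comms = [
            Community(frozenset("ax"), 0.1),
            Community(frozenset("ay"), 0.1),
            Community(frozenset("bz"), 0.1),
        ]
        df = map_clique_spans([Clique(frozenset("abc"))], self.HIER, comms)
        assert df.loc[0, "communities_touched"] == 3

    def test_missing_member_rejected(self):
        with pytest.raises(ValueError):
            map_clique_spans([Clique(frozenset("zzz"))], self.HIER, [])

    def test_identical_collections_all_shared(self):
        cl = [Clique(frozenset("abc"), "x"), Clique(frozenset("bcd"), "x")]
        cl2 = [Clique(frozenset("abc"), "y"), Clique(frozenset("bcd"), "y")]
        regions = compare_cliques_across_cells({"x": cl, "y": cl2})
        assert set(regions) == {("x", "y")} and len(regions[("x", "y")]) == 2

    def test_disjoint_collections_all_specific(self):
        regions = compare_cliques_across_cells(
            {"x": [Clique(frozenset("abc"), "x")], "y": [Clique(frozenset("def"), "y")]}
        )
        assert set(regions) == {("x",), ("y",)}

    def test_three_cells_one_common_one_unique_each(self):
        common = frozenset("abc")
        per_cell = {
            cell: [Clique(common, cell), Clique(frozenset(u), cell)]
            for cell, u in (("x", "pqr"), ("y", "stu"), ("z", "vwx"))
        }
        regions = compare_cliques_across_cells(per_cell)
        assert len(regions[("x", "y", "z")]) == 1
        assert sum(len(v) for k, v in regions.items() if len(k) == 1) == 3


def _occurrence(tf, anchor_id):
    return MotifOccurrence("m", tf, anchor_id, 0, "+", 10.0, 1e-12)


class TestRegulatedGenes:
    STATES = IntervalSet(
        "s",
        [
            GenomicInterval("chr1", 0, 100, label="Strong_Enhancer"),
            GenomicInterval("chr1", 1000, 1100, label="Active_Promoter"),
        ],
    )
    TSS = IntervalSet("tss", [GenomicInterval("chr1", 1050, 1051, label="g")])

    def loops(self):
        return annotate_anchors(
            [Loop(GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 1000, 1100), 9)],
            self.STATES,
        )

    def test_all_tfs_present_yields_gene(self):
        occs = [_occurrence(tf, "chr1:0-100") for tf in ("A", "B")] + [
            _occurrence("C", "chr1:1000-1100")
        ]
        genes = regulated_genes(Clique(frozenset("ABC")), self.loops(), occs, self.TSS)
        assert genes == {"g"}

    def test_missing_tf_yields_empty(self):
        occs = [_occurrence(tf, "chr1:0-100") for tf in ("A", "B")]
        assert regulated_genes(Clique(frozenset("ABC")), self.loops(), occs, self.TSS) == set()

    def test_promoter_without_tss_yields_empty(self):
        tss_far = IntervalSet("tss", [GenomicInterval("chr2", 0, 1, label="g")])
        occs = [_occurrence(tf, "chr1:0-100") for tf in ("A", "B", "C")]
        assert regulated_genes(Clique(frozenset("ABC")), self.loops(), occs, tss_far) == set()

    def test_antitone_in_clique_size(self):
        occs = [_occurrence(tf, "chr1:0-100") for tf in ("A", "B", "C")]
        small = regulated_genes(Clique(frozenset("AB")), self.loops(), occs, self.TSS)
        large = regulated_genes(Clique(frozenset("ABCD")), self.loops(), occs, self.TSS)
        assert large <= small

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError):
            regulated_genes(Clique(frozenset("A")), self.loops(), [], IntervalSet("t", []))


class TestPatterns:
    def test_three_patterns(self):
        per_cell = {
            "x": [
                (frozenset("abc"), {"g1", "g2"}),
                (frozenset("pqrs"), {"g3"}),
            ],
            "y": [
                (frozenset("abc"), {"g1", "g2"}),
                (frozenset("pqrt"), {"g9"}),
            ],
            "z": [(frozenset("abc"), {"g7", "g8"})],
        }
        records = classify_clique_patterns(per_cell)
        by_pair = {(r["cell_a"], r["cell_b"], r["clique_a"]): r["pattern"] for r in records}
        assert by_pair[("x", "y", "a,b,c")] == "same-clique-same-genes"
        assert by_pair[("x", "z", "a,b,c")] == "same-clique-different-genes"
        assert by_pair[("x", "y", "p,q,r,s")] == "partial-TF-sharing"

    def test_unrelated_cliques_not_reported(self):
        per_cell = {
            "x": [(frozenset("abc"), set())],
            "y": [(frozenset("xyz"), set())],
        }
        assert classify_clique_patterns(per_cell) == []


def ranksum_enumeration_p(within, between):
    """Oracle: exact one-sided rank-sum p by enumerating all group splits."""
    pooled = sorted(within + between, reverse=True)
    obs = sum(
        sum(1 for b in between if w > b) + 0.5 * sum(1 for b in between if w == b)
        for w in within
    )
    n = len(within)
    count = total = 0
    for combo in combinations(range(len(pooled)), n):
        w = [pooled[i] for i in combo]
        b = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(
            sum(1 for y in b if x > y) + 0.5 * sum(1 for y in b if x == y) for x in w
        )
        total += 1
        if u >= obs - 1e-12:
            count += 1
    return count / total


class TestExpressionCoherence:
    def expr(self, rows):
        return pd.DataFrame(rows).T

    def test_perfect_correlation(self):
        expr = self.expr(
            {"A": [1, 2, 3], "B": [10, 20, 30], "C": [3, 2, 1], "D": [9, 4, 1]}
        )
        res = expression_coherence(
            [Clique(frozenset("AB")), Clique(frozenset("CD"))], expr
        )
        # monotone pairs: rho(A,B) = rho(C,D) = 1; anti-monotone across: rho(A,C) = -1
        assert all(r == pytest.approx(1.0) for r in res.within_pair_correlations)
        assert any(r == pytest.approx(-1.0) for r in res.between_pair_correlations)

    def test_exact_wilcoxon_matches_enumeration(self):
        rng = np.random.default_rng(0)  # tie-free Spearman values at this seed
        expr = self.expr({t: rng.normal(size=8) for t in "ABCD"})
        cliques = [Clique(frozenset("AB")), Clique(frozenset("CD"))]
        res = expression_coherence(cliques, expr)
        assert len(set(res.within_pair_correlations + res.between_pair_correlations)) == 6
        assert res.wilcoxon_p == pytest.approx(
            ranksum_enumeration_p(
                res.within_pair_correlations, res.between_pair_correlations
            )
        )

    def test_low_noise_fixture_recovers_coherence(self, fixture_config, network_truth):
        cliques = [Clique(frozenset(c)) for c in fixture_config.planted_cliques]
        expr = network_truth.expression_by_cell["cellA"]
        res = expression_coherence(cliques, expr)
        assert res.wilcoxon_p < 0.05

    def test_too_few_samples_rejected(self):
        expr = self.expr({"A": [1, 2], "B": [2, 1]})
        with pytest.raises(ValueError):
            expression_coherence([Clique(frozenset("AB"))], expr)

    def test_missing_tf_rejected(self):
        expr = self.expr({"A": [1, 2, 3]})
        with pytest.raises(ValueError):
            expression_coherence([Clique(frozenset("AB"))], expr)
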