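import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from menc import (ComputationError, GeneSet, MutationMatrix,
                  build_merged_graph, compute_mutation_scores, extract_semilocal,
                  rank_drivers, score_gene)
from menc.degs import DEGSet
from menc.network import MergedGraph, Role

from conftest import random_attributed_graph
from _oracle import naive_score


def deg_set(*genes):
    members = frozenset(genes)
    return DEGSet(cohort=members, per_patient={"p0": members}, threshold=1.0)


def path_graph(*nodes):
    g = nx.Graph()
    nx.add_path(g, nodes)
    return g


def unit_matrix(genes, n_patients=3, rng=None):
    """Each gene mutated in one patient (round-robin), so scores are defined."""
    values = np.zeros((len(genes), n_patients), dtype=np.int8)
    for i in range(len(genes)):
        values[i, i % n_patients] = 1
    return MutationMatrix(list(genes), [f"p{j}" for j in range(n_patients)], values)


class TestMergedGraph:
    def test_intermediate_non_member_breaks_the_path(self):
        g = build_merged_graph(path_graph("A", "B", "C"),
                               GeneSet("mut", {"A"}), deg_set("C"))
        assert set(g.graph.nodes) == {"A", "C"}
        assert g.graph.number_of_edges() == 0

    def test_gene_in_both_sets_gets_both_role(self):
        g = build_merged_graph(path_graph("A", "B", "C"),
                               GeneSet("mut", {"A", "B"}), deg_set("B", "C"))
        assert g.role["B"] is Role.BOTH
        assert set(map(frozenset, g.graph.edges)) == {frozenset("AB"), frozenset("BC")}

    def test_genes_absent_from_ppi_are_dropped(self):
        g = build_merged_graph(path_graph("A", "B"),
                               GeneSet("mut", {"A", "ZZZ"}), deg_set("B"))
        assert "ZZZ" not in g.graph

    def test_empty_overlap_rejected(self):
        with pytest.raises(ComputationError):
            build_merged_graph(path_graph("A", "B"),
                               GeneSet("mut", {"X"}), deg_set("Y"))

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_every_merged_edge_exists_in_ppi(self, seed):
        rng = np.random.default_rng(seed)
        ppi = nx.gnp_random_graph(20, 0.2, seed=int(rng.integers(2**31)))
        ppi = nx.relabel_nodes(ppi, {i: f"n{i}" for i in ppi.nodes})
        nodes = list(ppi.nodes)
        mut = set(rng.choice(nodes, size=6, replace=False))
        degs = set(rng.choice(nodes, size=6, replace=False))
        g = build_merged_graph(ppi, GeneSet("m", mut), deg_set(*degs))
        kept = mut | degs
        for a, b in g.graph.edges:
            assert ppi.has_edge(a, b) and a in kept and b in kept
        # and no qualifying ppi edge is missed
        for a, b in ppi.edges:
            if a in kept and b in kept:
                assert g.graph.has_edge(a, b)


class TestExtractSemilocal:
    def test_isolated_source(self):
        g = MergedGraph(graph=nx.Graph([("v", "x")]), role={"v": Role.MUTATED,
                                                            "x": Role.DEG})
        g.graph.add_node("v2")
        g.role["v2"] = Role.MUTATED
        net = extract_semilocal(g, "v2")
        assert set(net.graph.nodes) == {"v2"}
        assert net.graph.number_of_edges() == 0

    def test_two_step_cutoff_on_a_path(self):
        g = MergedGraph(graph=path_graph("v", "a", "b", "c"),
                        role={x: Role.MUTATED for x in "vabc"})
        net = extract_semilocal(g, "v")
        assert set(net.graph.nodes) == {"v", "a", "b"}

    def test_non_mutated_source_rejected(self):
        g = MergedGraph(graph=path_graph("v", "a"),
                        role={"v": Role.DEG, "a": Role.MUTATED})
        with pytest.raises(ComputationError):
            extract_semilocal(g, "v")

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_node_set_matches_bfs_to_depth_two(self, seed):
        rng = np.random.default_rng(seed)
        merged, scores, m, source = random_attributed_graph(rng)
        net = extract_semilocal(merged, source)
        # independent BFS oracle
        depth = {source: 0}
        frontier = [source]
        while frontier:
            nxt = []
            for x in frontier:
                if depth[x] == 2:
                    continue
                for y in merged.graph[x]:
                    if y not in depth:
                        depth[y] = depth[x] + 1
                        nxt.append(y)
            frontier = nxt
        assert set(net.graph.nodes) == set(depth)


class TestScoreGene:
    def test_isolated_source_scores_zero(self):
        g = MergedGraph(graph=nx.Graph(), role={"v": Role.MUTATED})
        g.graph.add_node("v")
        net = extract_semilocal(g, "v")
        m = unit_matrix(["v"])
        scores = compute_mutation_scores(m)
        assert score_gene(net, scores, m) == 0.0

    def test_hand_evaluated_mutated_deg_pair(self, make_semilocal):
        # v (mutated) -- u (DEG):
        #   score(v) = deg(v) + b(u) = 1 + c(v);  c(v) = deg(u) = 1  =>  2
        net = make_semilocal("v", [("v", "u")],
                             {"v": Role.MUTATED, "u": Role.DEG})
        m = unit_matrix(["v", "u"])
        scores = compute_mutation_scores(m)
        assert score_gene(net, scores, m) == pytest.approx(2.0)
        assert naive_score(net, scores, m) == pytest.approx(2.0)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 2**31 - 1),
           st.sampled_from(["gravity", "literal"]),
           st.sampled_from(["literal", "nw"]),
           st.sampled_from(["degree", "two_hop"]))
    def test_matches_naive_oracle(self, seed, mif_mode, c_variant, neighbor_count):
        rng = np.random.default_rng(seed)
        merged, scores, m, source = random_attributed_graph(rng)
        net = extract_semilocal(merged, source)
        fast = score_gene(net, scores, m, mif_mode=mif_mode,
                          c_variant=c_variant, neighbor_count=neighbor_count)
        slow = naive_score(net, scores, m, mif_mode=mif_mode,
                           c_variant=c_variant, neighbor_count=neighbor_count)
        assert fast == pytest.approx(slow, rel=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_score_at_least_local_degree(self, seed):
        rng = np.random.default_rng(seed)
        merged, scores, m, source = random_attributed_graph(rng)
        net = extract_semilocal(merged, source)
        assert score_gene(net, scores, m) >= net.graph.degree(source)

    def test_adding_a_deg_neighbor_never_decreases_score(self, make_semilocal):
        roles = {"v": Role.MUTATED, "a": Role.DEG, "b": Role.MUTATED}
        m = unit_matrix(["v", "a", "b", "z"])
        scores = compute_mutation_scores(m)
        before = score_gene(make_semilocal("v", [("v", "a"), ("v", "b")], roles),
                            scores, m)
        roles2 = dict(roles, z=Role.DEG)
        after = score_gene(make_semilocal("v", [("v", "a"), ("v", "b"), ("v", "z")],
                                          roles2), scores, m)
        assert after >= before

    def test_both_role_scores_higher_than_single_role(self, make_semilocal):
        # same topology, neighbor u as DEG-only vs BOTH: the dual role adds
        # the mutation branch on top of the DEG branch.
        edges = [("v", "u"), ("u", "w")]
        m = unit_matrix(["v", "u", "w"])
        scores = compute_mutation_scores(m)
        single = score_gene(make_semilocal(
            "v", edges, {"v": Role.MUTATED, "u": Role.DEG, "w": Role.DEG}),
            scores, m)
        dual = score_gene(make_semilocal(
            "v", edges, {"v": Role.MUTATED, "u": Role.BOTH, "w": Role.DEG}),
            scores, m)
        assert dual > single


class TestRankDrivers:
    def _rank(self, merged, m):
        scores = compute_mutation_scores(m)
        return rank_drivers(merged, scores, m)

    def test_single_mutated_node(self):
        g = MergedGraph(graph=path_graph("v", "a"),
                        role={"v": Role.MUTATED, "a": Role.DEG})
        r = self._rank(g, unit_matrix(["v", "a"]))
        assert len(r) == 1 and r.entries[0].gene == "v" and r.entries[0].rank == 1

    def test_symmetric_tie_broken_alphabetically(self):
        # B -- X -- A with X a DEG: A and B have identical score and M(i)
        g = MergedGraph(graph=path_graph("B", "X", "A"),
                        role={"A": Role.MUTATED, "B": Role.MUTATED, "X": Role.DEG})
        values = np.array([[1, 0], [0, 1], [0, 0]])
        m = MutationMatrix(["A", "B", "X"], ["p1", "p2"], values)
        r = self._rank(g, m)
        assert r.genes() == ["A", "B"]

    def test_hub_outranks_peripheral_gene(self):
        # mutated hub wired to many DEGs vs a degree-1 mutated gene
        g = nx.star_graph(["H", "d1", "d2", "d3", "d4", "d5"])
        g.add_edge("L", "d5")
        roles = {"H": Role.MUTATED, "L": Role.MUTATED}
        roles.update({f"d{i}": Role.DEG for i in range(1, 6)})
        merged = MergedGraph(graph=g, role=roles)
        m = unit_matrix(["H", "L"] + [f"d{i}" for i in range(1, 6)])
        r = self._rank(merged, m)
        assert r.genes().index("H") < r.genes().index("L")

    def test_ranking_is_deterministic(self):
        rng = np.random.default_rng(123)
        merged, scores, m, _ = random_attributed_graph(rng, max_nodes=12)
        a = rank_drivers(merged, scores, m)
        b = rank_drivers(merged, scores, m)
        assert a.entries == b.entries

    def test_scores_non_increasing_and_ranks_contiguous(self):
        rng = np.random.default_rng(7)
        merged, scores, m, _ = random_attributed_graph(rng, max_nodes=14)
        r = rank_drivers(merged, scores, m)
        assert [e.rank for e in r] == list(range(1, len(r) + 1))
        s = [e.score for e in r]
        assert all(a >= b for a, b in zip(s, s[1:]))
        assert set(r.genes()) == set(merged.mutated_nodes())
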