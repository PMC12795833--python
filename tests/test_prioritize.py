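"""Centrality metrics, process representation, and consensus selection."""

from math import comb, isclose

import networkx as nx
import numpy as np
import pytest

from cytoreg.enrichment import ContingencyCounts, hypergeom_tail
from cytoreg.graph import AnnotationTable, GeneSet, GraphError, KnowledgeGraph, Node
from cytoreg.prioritize import (
    CentralityScores,
    betweenness_centrality,
    cytokine_centralities,
    degree_centrality,
    process_representation,
    rank_and_select,
)
from cytoreg.templates import Subnetwork, reconstruct

from conftest import make_node
from _oracles import brute_force_betweenness


def protein_chain_net(*edges):
    """Consolidated-network wrapper around explicit protein-level edges."""
    g = KnowledgeGraph()
    ids = {nid for edge in edges for nid in edge[:2]}
    for nid in sorted(ids):
        g.add_node(make_node(nid, kind="protein"))
    for source, target, itype in edges:
        g.add_edge(source, target, itype)
    return Subnetwork(g, {nid: {"source_cytokine"} for nid in ids})


class TestDegree:
    def test_isolated_node_zero(self):
        g = KnowledgeGraph()
        g.add_node(make_node("A", kind="protein"))
        net = Subnetwork(g, {})
        assert degree_centrality(net, ["A"]).degree["A"] == 0

    def test_star_center_counts_leaves(self):
        net = protein_chain_net(
            *[("C", f"L{i}", "activity_regulation") for i in range(4)]
        )
        assert degree_centrality(net, ["C"]).degree["C"] == 4

    def test_opposite_direction_typed_edges_both_counted(self):
        net = protein_chain_net(
            ("A", "B", "activity_regulation"),
            ("B", "A", "transport_regulation"),
        )
        assert degree_centrality(net, ["A"]).degree["A"] == 2

    def test_multi_typed_edges_to_same_neighbor_each_count(self):
        net = protein_chain_net(
            ("A", "B", "activity_regulation"),
            ("A", "B", "transport_regulation"),
            ("A", "B", "degradation_regulation"),
        )
        assert degree_centrality(net, ["A"]).degree["A"] == 3

    def test_degree_equals_edge_list_recount(self):
        rng = np.random.default_rng(42)
        from conftest import random_typed_graph

        g = random_typed_graph(rng)
        net = Subnetwork(g, {})
        for nid in g.nodes:
            recount = sum(
                1 for e in g.edges if nid in (e.source, e.target)
            ) + sum(1 for e in g.edges if e.source == nid and e.target == nid)
            assert degree_centrality(net, [nid]).degree[nid] == recount

    def test_unknown_node_rejected(self):
        net = protein_chain_net(("A", "B", "activity_regulation"))
        with pytest.raises(GraphError, match="ZZ"):
            degree_centrality(net, ["ZZ"])


class TestBetweenness:
    def test_path_middle_one_endpoints_zero(self):
        net = protein_chain_net(
            ("A", "B", "activity_regulation"),
            ("B", "C", "activity_regulation"),
        )
        bc = betweenness_centrality(net).betweenness
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_center_is_pair_count(self):
        net = protein_chain_net(
            *[("C", f"L{i}", "activity_regulation") for i in range(4)]
        )
        bc = betweenness_centrality(net).betweenness
        assert bc["C"] == comb(4, 2)
        assert all(bc[f"L{i}"] == 0.0 for i in range(4))

    def test_four_cycle_split_evenly(self):
        net = protein_chain_net(
            ("A", "B", "activity_regulation"),
            ("B", "C", "activity_regulation"),
            ("C", "D", "activity_regulation"),
            ("D", "A", "activity_regulation"),
        )
        bc = betweenness_centrality(net).betweenness
        assert all(isclose(v, 0.5) for v in bc.values())

    def test_direction_and_multiplicity_ignored(self):
        # projection is undirected and simple: antiparallel + multi-typed
        # edges act as a single link
        net = protein_chain_net(
            ("A", "B", "activity_regulation"),
            ("B", "A", "transport_regulation"),
            ("B", "C", "activity_regulation"),
            ("B", "C", "degradation_regulation"),
        )
        bc = betweenness_centrality(net).betweenness
        assert bc["B"] == 1.0

    @pytest.mark.parametrize("seed", range(30))
    def test_agrees_with_all_shortest_paths_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2**31)))
        kg = KnowledgeGraph()
        for v in g.nodes:
            kg.add_node(make_node(f"P{v:02d}", kind="protein"))
        for u, v in g.edges:
            kg.add_edge(f"P{u:02d}", f"P{v:02d}", "activity_regulation")
        net = Subnetwork(kg, {})
        ours = betweenness_centrality(net).betweenness
        expected = brute_force_betweenness(kg.undirected_projection())
        for nid in kg.nodes:
            assert isclose(ours[nid], expected[nid], abs_tol=1e-9), nid

    @pytest.mark.parametrize("seed", range(5))
    def test_tree_total_equals_pairs_with_intermediates(self, seed):
        tree = nx.random_labeled_tree(10, seed=seed)
        kg = KnowledgeGraph()
        for v in tree.nodes:
            kg.add_node(make_node(f"P{v:02d}", kind="protein"))
        for u, v in tree.edges:
            kg.add_edge(f"P{u:02d}", f"P{v:02d}", "activity_regulation")
        bc = betweenness_centrality(Subnetwork(kg, {})).betweenness
        n_pairs_with_intermediate = sum(
            1
            for i, u in enumerate(sorted(tree))
            for v in sorted(tree)[i + 1 :]
            if nx.shortest_path_length(tree, u, v) >= 2
        )
        # on a tree each such pair has a unique path: total pass-throughs
        # equal path length minus one, summed; equivalently count each
        # intermediate of each pair once
        total_intermediates = sum(
            nx.shortest_path_length(tree, u, v) - 1
            for i, u in enumerate(sorted(tree))
            for v in sorted(tree)[i + 1 :]
        )
        assert n_pairs_with_intermediate <= total_intermediates
        assert sum(bc.values()) == pytest.approx(total_intermediates)


@pytest.fixture
def term_space():
    """100 terms, 10 disease-associated; one cytokine annotated to 8 terms,
    5 of them disease terms."""
    background = frozenset({"CYT1", "CYT2", *(f"G{i}" for i in range(5))})
    terms = {}
    for i in range(100):
        term_id = f"GO:{i:04d}"
        genes = {"G0"}
        if i < 10:  # disease terms
            if i < 5:
                genes.add("CYT1")  # 5 disease terms annotate CYT1
        else:
            if i < 13:
                genes.add("CYT1")  # 3 background terms annotate CYT1
        terms[term_id] = (f"t{i}", frozenset(genes))
    asd_terms = {f"GO:{i:04d}" for i in range(10)}
    return AnnotationTable(terms, background), asd_terms


class TestProcessRepresentation:
    def test_unannotated_cytokine_p_one(self, term_space):
        table, asd_terms = term_space
        reps = process_representation(
            GeneSet("c", frozenset({"CYT2"})), asd_terms, table
        )
        (rep,) = reps
        assert rep.n_asd_processes == 0
        assert rep.p_value == 1.0

    def test_all_terms_disease_forces_p_one(self, term_space):
        table, _ = term_space
        reps = process_representation(
            GeneSet("c", frozenset({"CYT1"})), set(table.terms), table
        )
        (rep,) = reps
        assert rep.counts.k == rep.counts.n
        assert rep.p_value == 1.0

    def test_worked_overlap_tail(self, term_space):
        table, asd_terms = term_space
        (rep,) = process_representation(
            GeneSet("c", frozenset({"CYT1"})), asd_terms, table
        )
        assert rep.counts == ContingencyCounts(100, 10, 8, 5)
        assert rep.p_value == pytest.approx(
            hypergeom_tail(ContingencyCounts(100, 10, 8, 5))
        )
        # independent tail recomputation
        from math import comb as C

        exact = sum(C(10, i) * C(90, 8 - i) for i in range(5, 9)) / C(100, 8)
        assert rep.p_value == pytest.approx(exact, rel=1e-12)

    def test_absent_cytokine_dropped_with_warning(self, term_space, caplog):
        table, asd_terms = term_space
        with caplog.at_level("WARNING"):
            reps = process_representation(
                GeneSet("c", frozenset({"CYT1", "NOTINBG"})), asd_terms, table
            )
        assert len(reps) == 1
        assert "NOTINBG" in caplog.text

    def test_unknown_disease_terms_rejected(self, term_space):
        table, _ = term_space
        with pytest.raises(ValueError, match="GO:XXXX"):
            process_representation(
                GeneSet("c", frozenset({"CYT1"})), {"GO:XXXX"}, table
            )


def scores_from(degree: dict, betweenness: dict) -> CentralityScores:
    return CentralityScores(degree=degree, betweenness=betweenness)


class TestRankAndSelect:
    def test_identical_lists_consensus_equals_candidates(self):
        deg = {"A": 3, "B": 2, "C": 1}
        ranking = rank_and_select(
            scores_from(deg, dict(deg)), [], k_degree=2, k_betweenness=2,
            process_top_k=2,
        )
        assert ranking.candidates == {"A", "B"}
        # all reps empty -> process list via top-k on ties resolves by symbol
        assert ranking.consensus <= ranking.candidates

    def test_disjoint_lists_union_and_empty_intersection(self):
        symbols = [f"S{i:02d}" for i in range(43)]
        deg = {s: 0 for s in symbols}
        betw = {s: 0.0 for s in symbols}
        for i, s in enumerate(symbols[:15]):
            deg[s] = 100 - i
        for i, s in enumerate(symbols[15:30]):
            betw[s] = 100.0 - i
        reps = []
        from cytoreg.prioritize import ProcessRepresentation

        for s in symbols[30:43]:
            reps.append(
                ProcessRepresentation(
                    symbol=s,
                    n_asd_processes=5,
                    counts=ContingencyCounts(10, 5, 5, 5),
                    p_value=1e-6,
                    p_bonferroni=1e-5,
                    fdr=1e-6,
                    significant=True,
                )
            )
        ranking = rank_and_select(scores_from(deg, betw), reps)
        assert len(ranking.candidates) == 43
        assert ranking.consensus == set()

    def test_k_larger_than_population_capped_with_warning(self, caplog):
        deg = {"A": 1, "B": 2}
        with caplog.at_level("WARNING"):
            ranking = rank_and_select(
                scores_from(deg, {"A": 1.0, "B": 2.0}), [], k_degree=10,
                k_betweenness=10,
            )
        assert "capped" in caplog.text
        assert ranking.top_degree == {"A", "B"}

    def test_ranks_dense_after_ties(self):
        deg = {"A": 5, "B": 5, "C": 3, "D": 1}
        ranking = rank_and_select(
            scores_from(deg, {s: 0.0 for s in deg}), [], k_degree=2,
            k_betweenness=2,
        )
        by_symbol = {r.symbol: r.degree_rank for r in ranking.rows}
        assert by_symbol == {"A": 1, "B": 1, "C": 2, "D": 3}

    def test_consensus_subset_of_each_list(self):
        rng = np.random.default_rng(3)
        symbols = [f"S{i:02d}" for i in range(30)]
        deg = {s: int(rng.integers(0, 50)) for s in symbols}
        betw = {s: float(rng.uniform(0, 50)) for s in symbols}
        ranking = rank_and_select(
            scores_from(deg, betw), [], k_degree=10, k_betweenness=10,
            process_top_k=10,
        )
        for top in (
            ranking.top_degree,
            ranking.top_betweenness,
            ranking.process_list,
        ):
            assert ranking.consensus <= top
            assert top <= ranking.candidates

    def test_removing_a_metric_grows_or_keeps_consensus(self):
        rng = np.random.default_rng(9)
        symbols = [f"S{i:02d}" for i in range(25)]
        deg = {s: int(rng.integers(0, 40)) for s in symbols}
        betw = {s: float(rng.uniform(0, 40)) for s in symbols}
        full = rank_and_select(
            scores_from(deg, betw), [], k_degree=8, k_betweenness=8,
            process_top_k=8,
        )
        two_metric = full.top_degree & full.top_betweenness
        assert full.consensus <= two_metric


class TestPlantedHubs:
    def test_hubs_reach_all_three_top_lists(self):
        from cytoreg.enrichment import enrich_gene_set
        from cytoreg.simulate import SynthConfig, generate_all

        config = SynthConfig(
            n_cytokines=12,
            n_receptors=6,
            n_asd_genes=15,
            n_mediators=10,
            n_other=40,
            n_hubs=2,
            paths_per_hub=30,
            paths_per_nonhub=2,
            noise_edges=10,
            n_go_terms=40,
            n_asd_terms=8,
            seed=20,
        )
        graph, truth, annotations, _ = generate_all(config)
        net, _ = reconstruct(graph)
        regulated = frozenset(
            net.graph.node(nid).symbol
            for nid, roles in net.roles.items()
            if "asd_target" in roles
        )
        sig_terms = {
            r.term_id
            for r in enrich_gene_set(GeneSet("q", regulated), annotations)
            if r.significant
        }
        scores = cytokine_centralities(net)
        reps = process_representation(
            GeneSet("c", frozenset(scores.degree)), sig_terms, annotations
        )
        ranking = rank_and_select(scores, reps, k_degree=5, k_betweenness=5)
        assert truth.hub_symbols <= ranking.top_degree
        assert truth.hub_symbols <= ranking.top_betweenness
        assert truth.hub_symbols <= ranking.process_list
        assert truth.hub_symbols <= ranking.consensus
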