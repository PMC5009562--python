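"""Pair-graph construction: structure subgraphs, IP tagging, linear chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddikernel.corpus_io import CandidatePairInstance, PasArc, blind_entities
from ddikernel.graphs import (
    EdgeWeightPolicy,
    assemble_pair_graph,
    build_dependency_subgraph,
    build_linear_subgraph,
    build_pair_graph,
    build_pas_subgraph,
    mark_shortest_path,
    to_dot,
)
from ddikernel.kernel import build_label_vocabulary, graph_to_matrices

from conftest import make_sentence

PAIR = CandidatePairInstance("d", "s", "e1", "e2")


def blinded_sentence(*args, **kwargs):
    return blind_entities(make_sentence(*args, **kwargs), PAIR)


class TestDependencySubgraph:
    def test_minimal_tree(self):
        sent = blinded_sentence(["a", "b"], heads=[0, 1], rels=["root", "nsubj"],
                                drugs=(1, 2))
        sub = build_dependency_subgraph(sent, PAIR)
        assert len(sub.vertices) == 3  # 2 words + 1 relation (root arc has none)
        assert len(sub.edges) == 2

    def test_s1_drugs_joined_through_by_relation(self, s1, s1_pair):
        sub = build_dependency_subgraph(blind_entities(s1, s1_pair), s1_pair)
        rel_labels = {tuple(v.labels) for v in sub.vertices if v.kind == "relation"}
        assert ("prep_by",) in rel_labels
        # drug1 -> [prep_by] -> drug2 is a directed path of length 2
        by_vids = [v.vid for v in sub.vertices if v.kind == "relation" and v.labels == ["prep_by"]]
        edges = {(e.src, e.dst) for e in sub.edges}
        assert (sub.drug1_vid, by_vids[0]) in edges
        assert (by_vids[0], sub.drug2_vid) in edges

    def test_no_arcs_gives_isolated_word_vertices(self):
        sent = blinded_sentence(["a", "b", "c"], drugs=(1, 3))
        sub = build_dependency_subgraph(sent, PAIR)
        assert len(sub.vertices) == 3
        assert sub.edges == []

    def test_cyclic_arcs_rejected(self):
        sent = blinded_sentence(["a", "b"], heads=[2, 1], rels=["dep", "dep"],
                                drugs=(1, 2))
        with pytest.raises(ValueError, match="cycle"):
            build_dependency_subgraph(sent, PAIR)

    def test_vertex_count_is_tokens_plus_arcs(self, s1, s1_pair):
        sub = build_dependency_subgraph(blind_entities(s1, s1_pair), s1_pair)
        non_root_arcs = sum(1 for a in s1.dep_arcs if a.head != 0)
        assert len(sub.vertices) == len(s1.tokens) + non_root_arcs


class TestPasSubgraph:
    def test_single_arc(self):
        sent = blinded_sentence(["a", "b", "c"], drugs=(1, 3),
                                pas=[(2, "ARG1", 1)])
        sub = build_pas_subgraph(sent, PAIR)
        assert len(sub.vertices) == 4  # 3 words + 1 relation vertex
        assert len(sub.edges) == 2

    def test_relation_label_is_predicate_and_role(self):
        sent = blinded_sentence(["a", "by", "c"], drugs=(1, 3),
                                pas=[(2, "ARG2", 3)])
        sub = build_pas_subgraph(sent, PAIR)
        rels = [v for v in sub.vertices if v.kind == "relation"]
        assert rels[0].labels == ["by_arg2"]

    def test_shared_argument_word_vertex(self):
        # one token is the argument of two predicates: two relation vertices,
        # one shared word vertex
        sent = blinded_sentence(["a", "p1", "x", "p2", "b"], drugs=(1, 5),
                                pas=[(2, "ARG1", 3), (4, "ARG1", 3)])
        sub = build_pas_subgraph(sent, PAIR)
        assert sum(1 for v in sub.vertices if v.kind == "relation") == 2
        word_targets = {e.dst for e in sub.edges} - {v.vid for v in sub.vertices if v.kind == "relation"}
        assert len(word_targets) == 1

    def test_empty_pas_advises_dependency_mode(self):
        sent = blinded_sentence(["a", "b"], drugs=(1, 2))
        with pytest.raises(ValueError, match="dependency-only"):
            build_pas_subgraph(sent, PAIR)

    def test_s1_path_runs_through_inhibition_secretion_by(self, s1, s1_pair):
        graph = build_pair_graph(blind_entities(s1, s1_pair), s1_pair, "PAS")
        ip_words = {
            v.labels[0]
            for v in graph.vertices
            if v.kind == "word" and v.labels[0].endswith("_IP")
        }
        assert {"inhibition_IP", "of_IP", "secretion_IP", "drug1_IP", "by_IP",
                "drug2_IP"} <= ip_words


class TestMarkShortestPath:
    def test_chain_fully_tagged_and_on_path_weights(self):
        sent = blinded_sentence(["a", "b"], heads=[0, 1], rels=["root", "rel"],
                                drugs=(1, 2))
        sub = mark_shortest_path(build_dependency_subgraph(sent, PAIR))
        assert all(lab.endswith("_IP") for v in sub.vertices for lab in v.labels)
        assert [e.weight for e in sub.edges] == [0.9, 0.9]

    def test_side_branch_downweighted_and_untagged(self):
        # c hangs off b, off the a--b path
        sent = blinded_sentence(["a", "b", "c"], heads=[2, 0, 2],
                                rels=["nsubj", "root", "dobj"], drugs=(1, 2))
        sub = mark_shortest_path(build_dependency_subgraph(sent, PAIR))
        by_label = {tuple(v.labels): v for v in sub.vertices}
        assert ("c", "NN") in by_label  # untagged
        assert ("drug1_IP", "NN_IP") in by_label
        adj = {}
        for e in sub.edges:
            adj[(e.src, e.dst)] = e.weight
        c_vid = by_label[("c", "NN")].vid
        branch_weights = [w for (s_, d_), w in adj.items() if c_vid in (s_, d_)]
        assert branch_weights and all(w == 0.3 for w in branch_weights)

    def test_tied_geodesics_all_tagged(self):
        # diamond: drug1 -> x -> drug2 and drug1 -> y -> drug2, equal length
        from ddikernel.graphs import Subgraph, Vertex, WeightedEdge

        vertices = [
            Vertex(0, "word", ["drug1"]), Vertex(1, "word", ["x"]),
            Vertex(2, "word", ["y"]), Vertex(3, "word", ["drug2"]),
        ]
        edges = [WeightedEdge(0, 1, 0.0), WeightedEdge(1, 3, 0.0),
                 WeightedEdge(0, 2, 0.0), WeightedEdge(2, 3, 0.0)]
        sub = mark_shortest_path(Subgraph(vertices, edges, 0, 3))
        assert all(v.labels[0].endswith("_IP") for v in sub.vertices)
        assert all(e.weight == 0.9 for e in sub.edges)

    def test_disconnected_pair_gets_all_off_path(self):
        sent = blinded_sentence(["a", "b", "c"], heads=[2, 0, None],
                                rels=["nsubj", "root", "dep"], drugs=(1, 3))
        sub = mark_shortest_path(build_dependency_subgraph(sent, PAIR))
        assert all(not lab.endswith("_IP") for v in sub.vertices for lab in v.labels)
        assert all(e.weight == 0.3 for e in sub.edges)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_tree_ip_set_matches_bfs_oracle(self, seed):
        """On random trees the geodesic is unique and equals the tree path."""
        import networkx as nx

        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        heads = [0] + [int(rng.integers(0, i)) + 1 for i in range(1, n)]
        lemmas = [f"w{i}" for i in range(n)]
        d1, d2 = sorted(rng.choice(n, size=2, replace=False) + 1)
        sent = blinded_sentence(lemmas, heads=heads, rels=["r"] * n,
                                drugs=(int(d1), int(d2)))
        raw = build_dependency_subgraph(sent, PAIR)
        sub = mark_shortest_path(raw)
        g = nx.Graph([(e.src, e.dst) for e in raw.edges])
        g.add_nodes_from(v.vid for v in raw.vertices)
        oracle = set(nx.shortest_path(g, raw.drug1_vid, raw.drug2_vid))
        tagged = {v.vid for v in sub.vertices if v.labels[0].endswith("_IP")}
        assert tagged == oracle


class TestLinearSubgraph:
    def test_position_tags(self):
        sent = blinded_sentence(["a", "b", "c", "d", "e"], drugs=(2, 4))
        sub = build_linear_subgraph(sent, PAIR)
        tags = [v.labels[0].rsplit("_", 1)[1] for v in sub.vertices]
        assert tags == ["B", "B", "M", "A", "A"]

    def test_all_edges_linear_weight(self):
        sent = blinded_sentence(["a", "b", "c"], drugs=(1, 3))
        sub = build_linear_subgraph(sent, PAIR)
        assert [e.weight for e in sub.edges] == [0.9, 0.9]

    def test_two_token_pair_has_no_middle(self):
        sent = blinded_sentence(["a", "b"], drugs=(1, 2))
        sub = build_linear_subgraph(sent, PAIR)
        assert len(sub.edges) == 1
        assert not any("_M" in lab for v in sub.vertices for lab in v.labels)
        assert sub.vertices[0].labels[0] == "drug1_B"
        assert sub.vertices[1].labels[0] == "drug2_A"


class TestAssemble:
    def test_union_sizes_and_block_structure(self, s1, s1_pair):
        blinded = blind_entities(s1, s1_pair)
        structure = mark_shortest_path(build_dependency_subgraph(blinded, s1_pair))
        linear = build_linear_subgraph(blinded, s1_pair)
        graph = assemble_pair_graph(structure, linear)
        assert len(graph.vertices) == len(structure.vertices) + len(linear.vertices)
        assert len(graph.edges) == len(structure.edges) + len(linear.edges)
        # adjacency is block-diagonal: no edges cross the component boundary
        cut = len(structure.vertices)
        vocab = build_label_vocabulary([graph])
        A = graph_to_matrices(graph, vocab).A.toarray()
        assert not A[:cut, cut:].any()
        assert not A[cut:, :cut].any()

    def test_labels_preserved_verbatim(self, s1, s1_pair):
        blinded = blind_entities(s1, s1_pair)
        structure = mark_shortest_path(build_dependency_subgraph(blinded, s1_pair))
        linear = build_linear_subgraph(blinded, s1_pair)
        graph = assemble_pair_graph(structure, linear)
        merged = [v.labels for v in graph.vertices]
        assert merged == [v.labels for v in structure.vertices] + [
            v.labels for v in linear.vertices
        ]

    def test_dot_export_mentions_every_vertex(self, s1, s1_pair):
        graph = build_pair_graph(blind_entities(s1, s1_pair), s1_pair, "DEP")
        dot = to_dot(graph)
        assert dot.startswith("digraph")
        assert dot.count("->") == len(graph.edges)


class TestWeightPolicy:
    def test_weights_must_stay_below_one(self):
        with pytest.raises(ValueError):
            EdgeWeightPolicy(on_path=1.0)

    def test_acyclic_pair_graph_spectral_radius_below_one(self, s1, s1_pair):
        graph = build_pair_graph(blind_entities(s1, s1_pair), s1_pair, "DEP")
        vocab = build_label_vocabulary([graph])
        A = graph_to_matrices(graph, vocab).A.toarray()
        assert np.max(np.abs(np.linalg.eigvals(A))) < 1.0
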