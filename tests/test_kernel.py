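"""All-paths kernel: matrices, Neumann series, oracle equivalence, Gram/PSD."""

import numpy as np
import pytest
import scipy.sparse as sp

from ddikernel.graphs import PairGraph, Vertex, WeightedEdge
from ddikernel.kernel import (
    ConvergenceError,
    LabelVocabulary,
    brute_force_path_sum,
    build_label_vocabulary,
    feature_matrix_rows,
    gram_matrix,
    graph_feature_matrix,
    graph_to_matrices,
    kernel_value,
    spectral_radius,
)
from ddikernel.synthetic import generate_random_pair_graph


def graph_from(edges, labels):
    """labels: list of label lists per vertex; edges: (src, dst, w)."""
    vertices = [Vertex(i, "word", list(labs)) for i, labs in enumerate(labels)]
    return PairGraph(vertices, [WeightedEdge(*e) for e in edges])


def entry(G, vocab, i, j):
    return G.toarray()[vocab.index(i), vocab.index(j)]


class TestVocabulary:
    def test_union_sorted(self):
        g1 = graph_from([], [["a"], ["b"]])
        g2 = graph_from([], [["b"], ["c"]])
        assert build_label_vocabulary([g1, g2]).labels == ("a", "b", "c")

    def test_empty_graph_list_rejected(self):
        with pytest.raises(ValueError):
            build_label_vocabulary([])

    def test_order_stable(self):
        g = graph_from([], [["z"], ["a"], ["m"]])
        assert build_label_vocabulary([g]) == build_label_vocabulary([g])


class TestGraphToMatrices:
    def test_single_edge_weight(self):
        g = graph_from([(0, 1, 0.9)], [["a"], ["b"]])
        m = graph_to_matrices(g, build_label_vocabulary([g]))
        A = m.A.toarray()
        assert A[0, 1] == 0.9
        assert np.count_nonzero(A) == 1

    def test_two_labels_two_ones_in_column(self):
        g = graph_from([], [["a", "b"]])
        m = graph_to_matrices(g, build_label_vocabulary([g]))
        assert m.L.toarray()[:, 0].sum() == 2

    def test_edgeless_graph_zero_adjacency(self):
        g = graph_from([], [["a"], ["b"]])
        m = graph_to_matrices(g, build_label_vocabulary([g]))
        assert m.A.nnz == 0

    def test_unknown_label_errors_or_drops(self):
        g = graph_from([], [["a"], ["zzz"]])
        vocab = LabelVocabulary(["a"])
        with pytest.raises(KeyError):
            graph_to_matrices(g, vocab)
        m = graph_to_matrices(g, vocab, on_unknown="drop")
        assert m.L.toarray().sum() == 1


class TestFeatureMatrix:
    def test_single_edge_single_term(self):
        g = graph_from([(0, 1, 0.9)], [["a"], ["b"]])
        vocab = build_label_vocabulary([g])
        G = graph_feature_matrix(graph_to_matrices(g, vocab))
        assert entry(G, vocab, "a", "b") == pytest.approx(0.9)
        assert G.toarray().sum() == pytest.approx(0.9)

    def test_chain_accumulates_products(self):
        g = graph_from([(0, 1, 0.9), (1, 2, 0.9)], [["a"], ["b"], ["c"]])
        vocab = build_label_vocabulary([g])
        G = graph_feature_matrix(graph_to_matrices(g, vocab))
        assert entry(G, vocab, "a", "b") == pytest.approx(0.9)
        assert entry(G, vocab, "b", "c") == pytest.approx(0.9)
        assert entry(G, vocab, "a", "c") == pytest.approx(0.81)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_dag_matches_walk_enumeration_oracle(self, seed):
        g = generate_random_pair_graph(8, 0.3, acyclic=True, seed=seed)
        vocab = build_label_vocabulary([g])
        m = graph_to_matrices(g, vocab)
        closed = graph_feature_matrix(m).toarray()
        brute = brute_force_path_sum(m, max_len=8).toarray()
        np.testing.assert_allclose(closed, brute, atol=1e-9)

    def test_truncated_equals_closed_on_acyclic_at_depth(self):
        g = graph_from([(0, 1, 0.9), (1, 2, 0.3)], [["a"], ["b"], ["c"]])
        vocab = build_label_vocabulary([g])
        m = graph_to_matrices(g, vocab)
        closed = graph_feature_matrix(m).toarray()
        trunc = graph_feature_matrix(m, method="truncated", truncate_at=2).toarray()
        np.testing.assert_allclose(closed, trunc, atol=1e-12)

    def test_truncated_converges_monotonically(self):
        # 2-cycle: partial sums increase entrywise toward the closed form
        g = graph_from([(0, 1, 0.5), (1, 0, 0.5)], [["a"], ["b"]])
        vocab = build_label_vocabulary([g])
        m = graph_to_matrices(g, vocab)
        closed = graph_feature_matrix(m).toarray()
        prev = np.zeros_like(closed)
        for n in (1, 2, 5, 10, 40):
            t = graph_feature_matrix(m, method="truncated", truncate_at=n).toarray()
            assert (t >= prev - 1e-15).all()
            prev = t
        np.testing.assert_allclose(prev, closed, atol=1e-6)

    def test_two_cycle_limit_matches_geometric_series(self):
        w = 0.5
        g = graph_from([(0, 1, w), (1, 0, w)], [["a"], ["b"]])
        vocab = build_label_vocabulary([g])
        m = graph_to_matrices(g, vocab)
        brute = brute_force_path_sum(m, max_len=60).toarray()
        # walks a->a have weights w^2, w^4, ...: sum = w^2/(1-w^2)
        assert entry(sp.csr_matrix(brute), vocab, "a", "a") == pytest.approx(
            w * w / (1 - w * w), abs=1e-6
        )
        # walks a->b: w, w^3, ...: sum = w/(1-w^2)
        assert entry(sp.csr_matrix(brute), vocab, "a", "b") == pytest.approx(
            w / (1 - w * w), abs=1e-6
        )

    def test_divergent_spectral_radius_rejected(self):
        g = graph_from([(0, 1, 0.999999), (1, 0, 0.999999)], [["a"], ["b"]])
        vocab = build_label_vocabulary([g])
        with pytest.raises(ConvergenceError):
            graph_feature_matrix(graph_to_matrices(g, vocab))

    def test_empty_graph_brute_force_zero(self):
        g = graph_from([], [["a"], ["b"]])
        vocab = build_label_vocabulary([g])
        m = graph_to_matrices(g, vocab)
        assert brute_force_path_sum(m, max_len=5).nnz == 0

    def test_zero_weights_zero_everything(self):
        g = generate_random_pair_graph(6, 0.5, acyclic=True, seed=3)
        g = PairGraph(g.vertices, [WeightedEdge(e.src, e.dst, 0.0) for e in g.edges])
        vocab = build_label_vocabulary([g])
        G = graph_feature_matrix(graph_to_matrices(g, vocab))
        assert G.nnz == 0
        assert kernel_value(G, G) == 0.0


class TestKernelValue:
    def test_single_entry_squared(self):
        g = graph_from([(0, 1, 0.9)], [["a"], ["b"]])
        vocab = build_label_vocabulary([g])
        G = graph_feature_matrix(graph_to_matrices(g, vocab))
        assert kernel_value(G, G) == pytest.approx(0.81)

    def test_disjoint_label_sets_zero(self):
        g1 = graph_from([(0, 1, 0.9)], [["a"], ["b"]])
        g2 = graph_from([(0, 1, 0.9)], [["c"], ["d"]])
        vocab = build_label_vocabulary([g1, g2])
        G1 = graph_feature_matrix(graph_to_matrices(g1, vocab))
        G2 = graph_feature_matrix(graph_to_matrices(g2, vocab))
        assert kernel_value(G1, G2) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric(self, seed):
        g1 = generate_random_pair_graph(7, 0.4, seed=seed)
        g2 = generate_random_pair_graph(7, 0.4, seed=seed + 100)
        vocab = build_label_vocabulary([g1, g2])
        G1 = graph_feature_matrix(graph_to_matrices(g1, vocab))
        G2 = graph_feature_matrix(graph_to_matrices(g2, vocab))
        assert kernel_value(G1, G2) == pytest.approx(kernel_value(G2, G1))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kernel_value(sp.csr_matrix((2, 2)), sp.csr_matrix((3, 3)))


class TestGramMatrix:
    def test_identical_graphs_constant_matrix(self):
        g = graph_from([(0, 1, 0.9)], [["a"], ["b"]])
        vocab = build_label_vocabulary([g])
        K = gram_matrix([g, g], vocab)
        assert K.shape == (2, 2)
        assert np.allclose(K, K[0, 0])

    def test_psd_and_symmetric_on_random_graphs(self):
        graphs = [generate_random_pair_graph(8, 0.3, seed=s) for s in range(20)]
        vocab = build_label_vocabulary(graphs)
        K = gram_matrix(graphs, vocab)
        assert np.array_equal(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_permutation_equivariance(self):
        graphs = [generate_random_pair_graph(6, 0.4, seed=s) for s in range(4)]
        vocab = build_label_vocabulary(graphs)
        K = gram_matrix(graphs, vocab)
        perm = [2, 0, 3, 1]
        K_perm = gram_matrix([graphs[i] for i in perm], vocab)
        np.testing.assert_allclose(K_perm, K[np.ix_(perm, perm)])


class TestSpectralRadius:
    def test_nilpotent_acyclic_is_zero(self):
        g = generate_random_pair_graph(8, 0.5, acyclic=True, seed=1)
        vocab = build_label_vocabulary([g])
        assert spectral_radius(graph_to_matrices(g, vocab).A) < 1e-12

    def test_cyclic_generator_respects_target(self):
        g = generate_random_pair_graph(8, 0.4, acyclic=False, seed=5, target_rho=0.6)
        vocab = build_label_vocabulary([g])
        assert spectral_radius(graph_to_matrices(g, vocab).A) == pytest.approx(0.6, abs=1e-8)
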