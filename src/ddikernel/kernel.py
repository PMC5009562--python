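"""The all-paths graph kernel.

A PairGraph is represented by two matrices: a weighted adjacency matrix
A (|V| x |V|, A[i, j] = weight of the directed edge v_i -> v_j) and a binary
label-allocation matrix L (|labels| x |V|, L[i, j] = 1 iff vertex j carries
label i).  Provided the spectral radius of A is below one, the Neumann
series sums the weights of all non-empty directed walks between every vertex
pair,

    M = sum_{n>=1} A^n = (I - A)^{-1} - I,

and projecting into label space gives the graph feature matrix

    G[i, j] = sum_{u with label i} sum_{v with label j} M[u, v]  (G = L M L^T).

The kernel between two graphs over a shared label vocabulary is the
Frobenius inner product of their feature matrices,

    K(G', G'') = sum_ij G'[i, j] G''[i, j],

which is positive semi-definite by construction.  A brute-force walk
enumeration oracle is included for testing; note the series counts *walks*
(vertex repetition allowed), not simple paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graphs import PairGraph

__all__ = [
    "LabelVocabulary",
    "GraphMatrices",
    "build_label_vocabulary",
    "graph_to_matrices",
    "spectral_radius",
    "graph_feature_matrix",
    "feature_vector",
    "feature_matrix_rows",
    "kernel_value",
    "gram_matrix",
    "cross_gram_matrix",
    "brute_force_path_sum",
    "ConvergenceError",
]

# closed form requires rho(A) <= 1 - RHO_TOL
RHO_TOL = 1e-6


class ConvergenceError(ValueError):
    """Adjacency spectral radius too close to (or above) one."""


class LabelVocabulary:
    """Stable, lexicographically ordered label -> column index map shared
    across a corpus of graphs (so feature matrices are comparable)."""

    def __init__(self, labels) -> None:
        self._labels = tuple(sorted(set(labels)))
        self._index = {lab: i for i, lab in enumerate(self._labels)}

    def __len__(self) -> int:
        return len(self._labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelVocabulary) and self._labels == other._labels

    def __hash__(self) -> int:
        return hash(self._labels)

    @property
    def labels(self) -> tuple:
        return self._labels

    def index(self, label: str) -> int:
        return self._index[label]


def build_label_vocabulary(graphs) -> LabelVocabulary:
    if not graphs:
        raise ValueError("cannot build a vocabulary from zero graphs")
    labels: set[str] = set()
    for g in graphs:
        for v in g.vertices:
            labels.update(v.labels)
    return LabelVocabulary(labels)


@dataclass(frozen=True)
class GraphMatrices:
    A: sp.csr_matrix  # |V| x |V| weighted adjacency
    L: sp.csr_matrix  # |labels| x |V| binary allocation


def graph_to_matrices(
    graph: PairGraph, vocab: LabelVocabulary, on_unknown: str = "error"
) -> GraphMatrices:
    """Build (A, L) for one graph under a shared vocabulary.

    ``on_unknown='error'`` rejects labels outside the vocabulary;
    ``on_unknown='drop'`` silently omits them from L, so they contribute zero
    kernel mass (the treatment of labels seen only at prediction time).
    """
    n = graph.n_vertices
    rows, cols, data = [], [], []
    for e in graph.edges:
        if e.weight != 0.0:
            rows.append(e.src)
            cols.append(e.dst)
            data.append(e.weight)
    A = sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    lrows, lcols = [], []
    for v in graph.vertices:
        for lab in set(v.labels):
            if lab not in vocab:
                if on_unknown == "drop":
                    continue
                raise KeyError(f"label {lab!r} not in vocabulary")
            lrows.append(vocab.index(lab))
            lcols.append(v.vid)
    L = sp.csr_matrix(
        (np.ones(len(lrows)), (lrows, lcols)), shape=(len(vocab), n)
    )
    return GraphMatrices(A, L)


def spectral_radius(A: sp.spmatrix) -> float:
    n = A.shape[0]
    if n == 0 or A.nnz == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(A.toarray()))))


def graph_feature_matrix(
    m: GraphMatrices, method: str = "closed_form", truncate_at: int | None = None
) -> sp.csr_matrix:
    """Eq.-style feature matrix G = L ((I-A)^{-1} - I) L^T.

    ``method='closed_form'`` solves the linear system (I - A) X = L^T (no
    explicit inverse) and requires spectral radius < 1; ``method='truncated'``
    sums A^1 .. A^{truncate_at}.  On an acyclic graph both agree exactly once
    ``truncate_at`` reaches the longest path length.
    """
    A, L = m.A, m.L
    n = A.shape[0]
    if n == 0:
        return sp.csr_matrix((L.shape[0], L.shape[0]))
    if method == "closed_form":
        rho = spectral_radius(A)
        if rho > 1.0 - RHO_TOL:
            raise ConvergenceError(
                f"spectral radius {rho:.6f} too close to 1; the Neumann series "
                "does not converge for this graph"
            )
        Lt = L.T.toarray()
        X = np.linalg.solve(np.eye(n) - A.toarray(), Lt)  # (I-A)^{-1} L^T
        G = L @ (X - Lt)  # L M L^T with M = (I-A)^{-1} - I
        return sp.csr_matrix(G)
    if method == "truncated":
        if not truncate_at or truncate_at < 1:
            raise ValueError("truncated method needs truncate_at >= 1")
        S = sp.csr_matrix((n, n))
        P = sp.identity(n, format="csr")
        for _ in range(truncate_at):
            P = P @ A
            S = S + P
        return sp.csr_matrix((L @ S @ L.T))
    raise ValueError(f"unknown method {method!r}")


def kernel_value(g1: sp.spmatrix, g2: sp.spmatrix) -> float:
    """Frobenius inner product of two feature matrices (symmetric, >= 0 never
    guaranteed entrywise but PSD as a Gram form)."""
    if g1.shape != g2.shape:
        raise ValueError(
            f"feature matrices built over different vocabularies: "
            f"{g1.shape} vs {g2.shape}"
        )
    return float(g1.multiply(g2).sum())


def feature_vector(g: sp.spmatrix) -> sp.csr_matrix:
    """Flatten a feature matrix to a 1 x |labels|^2 sparse row, so Gram
    computation becomes a sparse matrix product."""
    return sp.csr_matrix(g.reshape(1, g.shape[0] * g.shape[1]))


def feature_matrix_rows(
    graphs,
    vocab: LabelVocabulary,
    method: str = "closed_form",
    truncate_at: int | None = None,
    on_unknown: str = "error",
) -> sp.csr_matrix:
    """Stack flattened feature matrices of many graphs into an n x |labels|^2
    sparse matrix F, so that K = F F^T."""
    rows = [
        feature_vector(
            graph_feature_matrix(
                graph_to_matrices(g, vocab, on_unknown=on_unknown),
                method=method,
                truncate_at=truncate_at,
            )
        )
        for g in graphs
    ]
    return sp.vstack(rows, format="csr")


def gram_matrix(graphs, vocab: LabelVocabulary, **kwargs) -> np.ndarray:
    """Gram matrix K[i, j] = K(G_i, G_j); no normalization is applied."""
    F = feature_matrix_rows(graphs, vocab, **kwargs)
    K = (F @ F.T).toarray()
    return np.asarray(K, dtype=float)


def cross_gram_matrix(
    F_rows: sp.csr_matrix, F_cols: sp.csr_matrix
) -> np.ndarray:
    """Kernel block between two stacks of flattened feature matrices."""
    if F_rows.shape[1] != F_cols.shape[1]:
        raise ValueError("feature stacks built over different vocabularies")
    return np.asarray((F_rows @ F_cols.T).toarray(), dtype=float)


def brute_force_path_sum(m: GraphMatrices, max_len: int) -> sp.csr_matrix:
    """Test oracle: explicitly enumerate every directed walk of length
    1..max_len, weight = product of edge weights, aggregated into label space
    exactly as the feature matrix.  Exponential; tiny graphs only."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    A = m.A
    n = A.shape[0]
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    coo = A.tocoo()
    for i, j, w in zip(coo.row, coo.col, coo.data):
        adj[i].append((int(j), float(w)))
    M = np.zeros((n, n))

    def walk(start: int, current: int, weight: float, length: int) -> None:
        for nxt, w in adj[current]:
            M[start, nxt] += weight * w
            if length + 1 < max_len:
                walk(start, nxt, weight * w, length + 1)

    for s in range(n):
        walk(s, s, 1.0, 0)
    G = m.L @ M @ m.L.T
    return sp.csr_matrix(G)
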