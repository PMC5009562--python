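"""Pair-specific weighted labelled graphs.

For one candidate drug pair a sentence is turned into a two-component graph:

* a *structure* component built from either the dependency tree or the
  predicate-argument structure (PAS).  Word vertices carry the token's lemma
  and POS tag; each syntactic/semantic arc becomes its own relation vertex
  sitting between head word and dependent word.  Every label on every vertex
  lying on a shortest undirected path between the two candidate drugs gets
  the suffix ``_IP`` (interaction path); edges on such paths are weighted
  0.9, all others 0.3.
* a *linear-order* component: the token chain, each word vertex labelled with
  lemma and POS suffixed by its position relative to the pair — ``_B`` before
  drug1, ``_M`` between (the drugs included), ``_A`` after drug2.  All edges
  are weighted 0.9.

The two components are disjoint; their union is the PairGraph the all-paths
kernel consumes.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace

from .corpus_io import CandidatePairInstance, ParsedSentence, span_head_token

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeWeightPolicy",
    "Vertex",
    "WeightedEdge",
    "Subgraph",
    "PairGraph",
    "build_dependency_subgraph",
    "build_pas_subgraph",
    "mark_shortest_path",
    "build_linear_subgraph",
    "assemble_pair_graph",
    "build_pair_graph",
    "to_networkx",
    "to_dot",
]

POSITION_SUFFIXES = ("IP", "B", "M", "A")


@dataclass(frozen=True)
class EdgeWeightPolicy:
    """Edge weights: shortest-path edges 0.9, other structure edges 0.3,
    linear-chain edges 0.9.  Weights strictly inside (0, 1) keep the Neumann
    series convergent on acyclic components."""

    on_path: float = 0.9
    off_path: float = 0.3
    linear: float = 0.9

    def __post_init__(self) -> None:
        for w in (self.on_path, self.off_path, self.linear):
            if not 0.0 <= w < 1.0:
                raise ValueError(f"edge weight {w} outside [0, 1)")


@dataclass
class Vertex:
    vid: int
    kind: str  # "word" | "relation"
    labels: list[str]
    token_index: int | None = None  # word vertices only; for SC substitution

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("vertex must carry at least one label")


@dataclass(frozen=True)
class WeightedEdge:
    src: int
    dst: int
    weight: float


@dataclass
class Subgraph:
    vertices: list[Vertex]
    edges: list[WeightedEdge]
    drug1_vid: int
    drug2_vid: int


@dataclass
class PairGraph:
    vertices: list[Vertex]
    edges: list[WeightedEdge]
    # drug1/drug2 word-vertex ids, per component
    pair_vids: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def copy(self) -> "PairGraph":
        return PairGraph(
            [replace(v, labels=list(v.labels)) for v in self.vertices],
            list(self.edges),
            dict(self.pair_vids),
        )


def _word_vertices(
    sentence: ParsedSentence,
) -> tuple[list[Vertex], dict[int, int]]:
    """One word vertex per visible token; labels [lemma, pos]."""
    vertices: list[Vertex] = []
    tok2vid: dict[int, int] = {}
    for tok in sentence.tokens:
        if tok.index in sentence.hidden_tokens:
            continue
        vid = len(vertices)
        labels = [tok.lemma.lower()]
        if tok.pos:
            labels.append(tok.pos)
        vertices.append(Vertex(vid, "word", labels, token_index=tok.index))
        tok2vid[tok.index] = vid
    return vertices, tok2vid


def _pair_head_vids(
    sentence: ParsedSentence, pair: CandidatePairInstance, tok2vid: dict[int, int]
) -> tuple[int, int]:
    h1 = span_head_token(sentence, sentence.entity(pair.e1))
    h2 = span_head_token(sentence, sentence.entity(pair.e2))
    if h1 > h2:
        h1, h2 = h2, h1
    return tok2vid[h1], tok2vid[h2]


def _check_acyclic_dep(sentence: ParsedSentence) -> None:
    head = {a.dependent: a.head for a in sentence.dep_arcs}
    for start in head:
        slow = start
        seen = set()
        while slow in head and head[slow] != 0:
            if slow in seen:
                raise ValueError(
                    f"sentence {sentence.sentence_id}: dependency arcs contain a cycle"
                )
            seen.add(slow)
            slow = head[slow]


def build_dependency_subgraph(
    sentence: ParsedSentence, pair: CandidatePairInstance
) -> Subgraph:
    """Dependency structure component (no IP tags or weights yet).

    One word vertex per token, one relation vertex per dependency arc
    (labelled with the relation name), edges directed
    head word -> relation vertex -> dependent word.
    """
    _check_acyclic_dep(sentence)
    vertices, tok2vid = _word_vertices(sentence)
    edges: list[WeightedEdge] = []
    for arc in sentence.dep_arcs:
        if arc.head == 0:
            continue  # the artificial root has no word vertex
        if arc.head in sentence.hidden_tokens or arc.dependent in sentence.hidden_tokens:
            continue
        rel = Vertex(len(vertices), "relation", [arc.label])
        vertices.append(rel)
        edges.append(WeightedEdge(tok2vid[arc.head], rel.vid, 0.0))
        edges.append(WeightedEdge(rel.vid, tok2vid[arc.dependent], 0.0))
    d1, d2 = _pair_head_vids(sentence, pair, tok2vid)
    return Subgraph(vertices, edges, d1, d2)


def build_pas_subgraph(
    sentence: ParsedSentence,
    pair: CandidatePairInstance,
    predicate_in_label: bool = True,
) -> Subgraph:
    """PAS structure component: relation vertices labelled
    ``<predicate-lemma>_<role>`` (e.g. ``by_arg2``), edges directed
    predicate word -> relation vertex -> argument-head word."""
    if not sentence.pas_arcs:
        raise ValueError(
            f"sentence {sentence.sentence_id} has no PAS arcs; "
            "use dependency-only mode for this corpus"
        )
    vertices, tok2vid = _word_vertices(sentence)
    edges: list[WeightedEdge] = []
    for arc in sentence.pas_arcs:
        if arc.predicate in sentence.hidden_tokens or arc.argument_head in sentence.hidden_tokens:
            continue
        role = arc.role.lower()
        if predicate_in_label:
            pred_lemma = sentence.tokens[arc.predicate - 1].lemma.lower()
            label = f"{pred_lemma}_{role}"
        else:
            label = role
        rel = Vertex(len(vertices), "relation", [label])
        vertices.append(rel)
        edges.append(WeightedEdge(tok2vid[arc.predicate], rel.vid, 0.0))
        edges.append(WeightedEdge(rel.vid, tok2vid[arc.argument_head], 0.0))
    d1, d2 = _pair_head_vids(sentence, pair, tok2vid)
    return Subgraph(vertices, edges, d1, d2)


def _bfs_distances(n: int, adj: dict[int, set[int]], source: int) -> list[float]:
    dist = [float("inf")] * n
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, ()):
            if dist[v] == float("inf"):
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def mark_shortest_path(
    subgraph: Subgraph, policy: EdgeWeightPolicy = EdgeWeightPolicy()
) -> Subgraph:
    """Tag shortest-path vertices with ``_IP`` and assign edge weights.

    Shortest paths are measured by edge count on the undirected view.  Every
    label of every vertex on *any* geodesic between the pair gets the ``_IP``
    suffix; edges on a geodesic get ``policy.on_path``, all others
    ``policy.off_path``.  A disconnected pair yields no tags and all edges
    off-path (logged, not fatal)."""
    n = len(subgraph.vertices)
    adj: dict[int, set[int]] = {}
    for e in subgraph.edges:
        adj.setdefault(e.src, set()).add(e.dst)
        adj.setdefault(e.dst, set()).add(e.src)
    d_from_1 = _bfs_distances(n, adj, subgraph.drug1_vid)
    d_from_2 = _bfs_distances(n, adj, subgraph.drug2_vid)
    total = d_from_1[subgraph.drug2_vid]

    if total == float("inf"):
        logger.warning(
            "candidate pair is disconnected in the structure graph; "
            "emitting all off-path weights"
        )
        on_vertices: set[int] = set()
    else:
        on_vertices = {
            v for v in range(n) if d_from_1[v] + d_from_2[v] == total
        }

    new_vertices = [
        replace(
            v,
            labels=[f"{lab}_IP" for lab in v.labels] if v.vid in on_vertices else list(v.labels),
        )
        for v in subgraph.vertices
    ]

    def on_geodesic(e: WeightedEdge) -> bool:
        if total == float("inf"):
            return False
        return (
            d_from_1[e.src] + 1 + d_from_2[e.dst] == total
            or d_from_1[e.dst] + 1 + d_from_2[e.src] == total
        )

    new_edges = [
        WeightedEdge(e.src, e.dst, policy.on_path if on_geodesic(e) else policy.off_path)
        for e in subgraph.edges
    ]
    return Subgraph(new_vertices, new_edges, subgraph.drug1_vid, subgraph.drug2_vid)


def build_linear_subgraph(
    sentence: ParsedSentence,
    pair: CandidatePairInstance,
    policy: EdgeWeightPolicy = EdgeWeightPolicy(),
) -> Subgraph:
    """Linear word-order component.

    Labels are lemma and POS suffixed with the position tag relative to the
    pair: ``_B`` before drug1, ``_M`` from drug1 through drug2, ``_A`` after
    drug2.  Consecutive visible tokens are linked left-to-right with weight
    ``policy.linear``."""
    h1 = span_head_token(sentence, sentence.entity(pair.e1))
    h2 = span_head_token(sentence, sentence.entity(pair.e2))
    if h1 > h2:
        h1, h2 = h2, h1
    vertices: list[Vertex] = []
    tok2vid: dict[int, int] = {}
    for tok in sentence.tokens:
        if tok.index in sentence.hidden_tokens:
            continue
        # drug1 itself carries _B and drug2 _A, so _M marks strictly-between
        tag = "B" if tok.index <= h1 else ("A" if tok.index >= h2 else "M")
        labels = [f"{tok.lemma.lower()}_{tag}"]
        if tok.pos:
            labels.append(f"{tok.pos}_{tag}")
        vid = len(vertices)
        vertices.append(Vertex(vid, "word", labels, token_index=tok.index))
        tok2vid[tok.index] = vid
    edges = [
        WeightedEdge(vertices[i].vid, vertices[i + 1].vid, policy.linear)
        for i in range(len(vertices) - 1)
    ]
    return Subgraph(vertices, edges, tok2vid[h1], tok2vid[h2])


def assemble_pair_graph(structure: Subgraph, linear: Subgraph) -> PairGraph:
    """Disjoint union of the two components (vids re-indexed, no cross edges)."""
    vertices: list[Vertex] = []
    edges: list[WeightedEdge] = []
    offsets = {}
    for name, sub in (("structure", structure), ("linear", linear)):
        offset = len(vertices)
        offsets[name] = offset
        for v in sub.vertices:
            vertices.append(replace(v, vid=v.vid + offset, labels=list(v.labels)))
        for e in sub.edges:
            edges.append(WeightedEdge(e.src + offset, e.dst + offset, e.weight))
    pair_vids = {
        "structure": (
            structure.drug1_vid + offsets["structure"],
            structure.drug2_vid + offsets["structure"],
        ),
        "linear": (
            linear.drug1_vid + offsets["linear"],
            linear.drug2_vid + offsets["linear"],
        ),
    }
    return PairGraph(vertices, edges, pair_vids)


def build_pair_graph(
    sentence: ParsedSentence,
    pair: CandidatePairInstance,
    structure: str = "DEP",
    policy: EdgeWeightPolicy = EdgeWeightPolicy(),
) -> PairGraph:
    """Convenience: blinded sentence -> complete PairGraph for one pair."""
    if structure == "DEP":
        sub = build_dependency_subgraph(sentence, pair)
    elif structure == "PAS":
        sub = build_pas_subgraph(sentence, pair)
    else:
        raise ValueError(f"unknown structure {structure!r}; expected DEP or PAS")
    sub = mark_shortest_path(sub, policy)
    linear = build_linear_subgraph(sentence, pair, policy)
    return assemble_pair_graph(sub, linear)


# ---------------------------------------------------------------------------
# Debug export
# ---------------------------------------------------------------------------

def to_networkx(graph: PairGraph):
    import networkx as nx

    g = nx.DiGraph()
    for v in graph.vertices:
        g.add_node(v.vid, kind=v.kind, labels="|".join(v.labels))
    for e in graph.edges:
        g.add_edge(e.src, e.dst, weight=e.weight)
    return g


def to_dot(graph: PairGraph) -> str:
    lines = ["digraph pairgraph {"]
    for v in graph.vertices:
        shape = "box" if v.kind == "relation" else "ellipse"
        label = "\\n".join(v.labels)
        lines.append(f'  v{v.vid} [label="{label}", shape={shape}];')
    for e in graph.edges:
        lines.append(f'  v{e.src} -> v{e.dst} [label="{e.weight:g}"];')
    lines.append("}")
    return "\n".join(lines)
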