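"""Shared fixtures.

``s1`` is the worked example used throughout: "The inhibition of
P-glycoprotein-mediated tubular secretion of Quinidine by Itraconazole."
Its dependency parse uses Stanford collapsed-style prepositional relations,
under which the two drugs are joined directly by a ``prep_by`` relation
(shortest dependency path "drug1 by drug2"), while the PAS path runs through
inhibition / of / secretion / of / by.
"""

from __future__ import annotations

import pytest

from ddikernel.corpus_io import (
    CandidatePairInstance,
    DependencyArc,
    EntityMention,
    ParsedSentence,
    PasArc,
    Token,
)

S1_WORDS = [
    # index, surface, lemma, pos, head, deprel
    (1, "The", "the", "DT", 2, "det"),
    (2, "inhibition", "inhibition", "NN", 0, "root"),
    (3, "of", "of", "IN", 2, "prep"),
    (4, "P-glycoprotein-mediated", "p-glycoprotein-mediated", "JJ", 6, "amod"),
    (5, "tubular", "tubular", "JJ", 6, "amod"),
    (6, "secretion", "secretion", "NN", 2, "prep_of"),
    (7, "of", "of", "IN", 6, "prep"),
    (8, "Quinidine", "quinidine", "NN", 6, "prep_of"),
    (9, "by", "by", "IN", 8, "prep"),
    (10, "Itraconazole", "itraconazole", "NN", 8, "prep_by"),
    (11, ".", ".", ".", 2, "punct"),
]

S1_PAS = [
    # predicate, role, argument head
    (3, "ARG1", 2),
    (3, "ARG2", 6),
    (7, "ARG1", 6),
    (7, "ARG2", 8),
    (9, "ARG1", 2),
    (9, "ARG2", 10),
]


@pytest.fixture
def s1() -> ParsedSentence:
    tokens = tuple(Token(i, surf, lemma, pos) for i, surf, lemma, pos, _, _ in S1_WORDS)
    dep = tuple(DependencyArc(head, i, rel) for i, _, _, _, head, rel in S1_WORDS)
    pas = tuple(PasArc(p, r, a) for p, r, a in S1_PAS)
    entities = (
        EntityMention("e1", 8, 8, "drug", "Quinidine"),
        EntityMention("e2", 10, 10, "drug", "Itraconazole"),
    )
    return ParsedSentence("s1", tokens, dep, pas, entities, relations={frozenset(("e1", "e2")): "DDI"})


@pytest.fixture
def s1_pair() -> CandidatePairInstance:
    return CandidatePairInstance("doc1", "s1", "e1", "e2", "DDI")


@pytest.fixture
def s1_conllu(tmp_path):
    """S1 as a CoNLL-U file plus an entity sidecar."""
    lines = ["# sent_id = s1"]
    for i, surf, lemma, pos, head, rel in S1_WORDS:
        lines.append(
            f"{i}\t{surf}\t{lemma}\t_\t{pos}\t_\t{head}\t{rel}\t_\t_"
        )
    path = tmp_path / "s1.conllu"
    path.write_text("\n".join(lines) + "\n\n")
    sidecar = tmp_path / "s1.entities.jsonl"
    sidecar.write_text(
        '{"doc_id": "doc1", "sentence_id": "s1", "entities": ['
        '{"id": "e1", "start_tok": 8, "end_tok": 8, "type": "drug", "name": "Quinidine"}, '
        '{"id": "e2", "start_tok": 10, "end_tok": 10, "type": "drug", "name": "Itraconazole"}], '
        '"relations": [{"e1": "e1", "e2": "e2", "label": "DDI"}]}\n'
    )
    return path, sidecar


def make_sentence(lemmas, heads=None, rels=None, drugs=(), sentence_id="s", pas=()):
    """Tiny sentence builder for unit tests: lemmas list, optional flat
    head/relation lists, drug token indices becoming single-token entities."""
    n = len(lemmas)
    tokens = tuple(Token(i + 1, lemmas[i], lemmas[i], "NN") for i in range(n))
    dep = ()
    if heads is not None:
        rels = rels or ["dep"] * n
        dep = tuple(
            DependencyArc(h, i + 1, r)
            for i, (h, r) in enumerate(zip(heads, rels))
            if h is not None
        )
    entities = tuple(
        EntityMention(f"e{k}", idx, idx, "drug", lemmas[idx - 1])
        for k, idx in enumerate(drugs, start=1)
    )
    return ParsedSentence(
        sentence_id, tokens, dep, tuple(PasArc(*a) for a in pas), entities
    )
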