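"""Reading, writing and validating pre-parsed annotated corpora.

The package consumes parser output (dependency trees, predicate-argument
structures) through two neutral formats:

* a JSON Lines dialect with one record per sentence, carrying tokens,
  dependency arcs, PAS arcs, entity mentions and gold relation labels;
* standard 10-column CoNLL-U for dependency-only input, with entities and
  relations supplied through a sidecar JSONL file.

It also owns candidate-pair enumeration (all drug pairs co-occurring in a
sentence, minus pairs of identically-named mentions) and entity blinding
(the candidate pair becomes ``drug1``/``drug2``, any other drug mention
becomes the generic ``drug``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Token",
    "DependencyArc",
    "PasArc",
    "EntityMention",
    "ParsedSentence",
    "AnnotatedDocument",
    "CandidatePairInstance",
    "CorpusParseError",
    "CorpusValidationError",
    "read_corpus",
    "write_corpus",
    "enumerate_candidate_pairs",
    "blind_entities",
    "span_head_token",
]

DDI = "DDI"
NDDI = "NDDI"


class CorpusParseError(ValueError):
    """Malformed record in a corpus file (carries the offending line number)."""


class CorpusValidationError(ValueError):
    """Structurally invalid sentence (dangling arc index, bad span, ...)."""


@dataclass(frozen=True)
class Token:
    index: int  # 1-based position in the sentence
    surface: str
    lemma: str
    pos: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise CorpusValidationError(f"token index must be >= 1, got {self.index}")
        if not self.lemma:
            raise CorpusValidationError(f"token {self.index} has an empty lemma")


@dataclass(frozen=True)
class DependencyArc:
    head: int  # 0 denotes the artificial root
    dependent: int
    label: str

    def __post_init__(self) -> None:
        if self.dependent < 1:
            raise CorpusValidationError("dependent index must be >= 1")
        if self.head == self.dependent:
            raise CorpusValidationError(f"self-loop dependency arc on token {self.head}")


@dataclass(frozen=True)
class PasArc:
    predicate: int
    role: str  # e.g. ARG1, ARG2
    argument_head: int

    def __post_init__(self) -> None:
        if self.predicate == self.argument_head:
            raise CorpusValidationError(f"PAS self-loop on token {self.predicate}")


@dataclass(frozen=True)
class EntityMention:
    id: str
    start_tok: int
    end_tok: int  # inclusive, 1-based
    etype: str
    name: str

    @property
    def token_span(self) -> range:
        return range(self.start_tok, self.end_tok + 1)


@dataclass(frozen=True)
class ParsedSentence:
    sentence_id: str
    tokens: tuple[Token, ...]
    dep_arcs: tuple[DependencyArc, ...] = ()
    pas_arcs: tuple[PasArc, ...] = ()
    entities: tuple[EntityMention, ...] = ()
    # gold relation labels keyed by the unordered entity-id pair; None when the
    # corpus carries no relation annotation at all
    relations: dict | None = None
    # token indices suppressed from graph construction (non-head tokens of
    # multi-token entity spans, set by blind_entities)
    hidden_tokens: frozenset = frozenset()

    def __post_init__(self) -> None:
        n = len(self.tokens)
        for i, tok in enumerate(self.tokens, start=1):
            if tok.index != i:
                raise CorpusValidationError(
                    f"sentence {self.sentence_id}: token index {tok.index} at position {i}"
                )
        seen_heads: dict[int, int] = {}
        for arc in self.dep_arcs:
            if arc.dependent > n or (arc.head > n):
                raise CorpusValidationError(
                    f"sentence {self.sentence_id}: dependency arc {arc.head}->{arc.dependent} "
                    f"outside 1..{n}"
                )
            if arc.dependent in seen_heads:
                raise CorpusValidationError(
                    f"sentence {self.sentence_id}: token {arc.dependent} has two heads"
                )
            seen_heads[arc.dependent] = arc.head
        for arc in self.pas_arcs:
            if not (1 <= arc.predicate <= n and 1 <= arc.argument_head <= n):
                raise CorpusValidationError(
                    f"sentence {self.sentence_id}: PAS arc {arc.predicate}->{arc.argument_head} "
                    f"outside 1..{n}"
                )
        for ent in self.entities:
            if not (1 <= ent.start_tok <= ent.end_tok <= n):
                raise CorpusValidationError(
                    f"sentence {self.sentence_id}: entity {ent.id} span "
                    f"{ent.start_tok}..{ent.end_tok} outside 1..{n}"
                )

    def entity(self, eid: str) -> EntityMention:
        for ent in self.entities:
            if ent.id == eid:
                return ent
        raise CorpusValidationError(f"entity {eid!r} not in sentence {self.sentence_id}")

    def dep_head_of(self, index: int) -> int | None:
        for arc in self.dep_arcs:
            if arc.dependent == index:
                return arc.head
        return None


@dataclass(frozen=True)
class AnnotatedDocument:
    doc_id: str
    sentences: tuple[ParsedSentence, ...]


@dataclass(frozen=True)
class CandidatePairInstance:
    doc_id: str
    sentence_id: str
    e1: str  # leftmost mention
    e2: str
    gold_label: str | None = None  # DDI / NDDI / None (unknown)

    def __post_init__(self) -> None:
        if self.e1 == self.e2:
            raise CorpusValidationError("candidate pair with identical entity ids")


# ---------------------------------------------------------------------------
# JSONL dialect
# ---------------------------------------------------------------------------

def _sentence_from_record(rec: dict) -> tuple[str, ParsedSentence]:
    tokens = tuple(
        Token(t["i"], t["surface"], t["lemma"], t.get("pos", "")) for t in rec["tokens"]
    )
    dep = tuple(
        DependencyArc(a["head"], a["dep"], a["label"]) for a in rec.get("dep", [])
    )
    pas = tuple(PasArc(a["pred"], a["role"], a["arg"]) for a in rec.get("pas", []))
    ents = tuple(
        EntityMention(e["id"], e["start_tok"], e["end_tok"], e.get("type", "drug"), e["name"])
        for e in rec.get("entities", [])
    )
    relations = None
    if "relations" in rec:
        relations = {
            frozenset((r["e1"], r["e2"])): r["label"] for r in rec["relations"]
        }
    sent = ParsedSentence(
        sentence_id=str(rec["sentence_id"]),
        tokens=tokens,
        dep_arcs=dep,
        pas_arcs=pas,
        entities=ents,
        relations=relations,
    )
    return str(rec["doc_id"]), sent


def _record_from_sentence(doc_id: str, s: ParsedSentence) -> dict:
    rec: dict = {
        "doc_id": doc_id,
        "sentence_id": s.sentence_id,
        "tokens": [
            {"i": t.index, "surface": t.surface, "lemma": t.lemma, "pos": t.pos}
            for t in s.tokens
        ],
        "dep": [{"head": a.head, "dep": a.dependent, "label": a.label} for a in s.dep_arcs],
        "pas": [
            {"pred": a.predicate, "role": a.role, "arg": a.argument_head}
            for a in s.pas_arcs
        ],
        "entities": [
            {
                "id": e.id,
                "start_tok": e.start_tok,
                "end_tok": e.end_tok,
                "type": e.etype,
                "name": e.name,
            }
            for e in s.entities
        ],
    }
    if s.relations is not None:
        rec["relations"] = [
            {"e1": min(pair), "e2": max(pair), "label": label}
            for pair, label in sorted(s.relations.items(), key=lambda kv: sorted(kv[0]))
        ]
    return rec


def _read_jsonl(path: Path) -> list[AnnotatedDocument]:
    order: list[str] = []
    by_doc: dict[str, list[ParsedSentence]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                doc_id, sent = _sentence_from_record(rec)
            except CorpusValidationError:
                raise
            except (KeyError, TypeError, ValueError) as exc:
                raise CorpusParseError(f"{path}: malformed record at line {lineno}: {exc}") from exc
            if doc_id not in by_doc:
                order.append(doc_id)
                by_doc[doc_id] = []
            by_doc[doc_id].append(sent)
    return [AnnotatedDocument(d, tuple(by_doc[d])) for d in order]


# ---------------------------------------------------------------------------
# CoNLL-U (dependency-only input)
# ---------------------------------------------------------------------------

def _read_conllu(path: Path, sidecar: Path | None = None) -> list[AnnotatedDocument]:
    """Parse standard 10-column CoNLL-U; pas_arcs are left empty.

    Entity mentions and relations may be supplied via a sidecar JSONL whose
    records are ``{"doc_id", "sentence_id", "entities": [...], "relations": [...]}``.
    """
    side: dict[str, dict] = {}
    if sidecar is not None:
        with open(sidecar, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    rec = json.loads(line)
                    side[str(rec["sentence_id"])] = rec

    docs_order: list[str] = []
    by_doc: dict[str, list[ParsedSentence]] = {}
    cur_tokens: list[Token] = []
    cur_arcs: list[DependencyArc] = []
    sent_id = None
    doc_id = "doc1"
    n_sent = 0

    def flush() -> None:
        nonlocal cur_tokens, cur_arcs, sent_id, n_sent
        if not cur_tokens:
            return
        n_sent += 1
        sid = sent_id if sent_id is not None else f"s{n_sent}"
        extra = side.get(sid, {})
        ents = tuple(
            EntityMention(e["id"], e["start_tok"], e["end_tok"], e.get("type", "drug"), e["name"])
            for e in extra.get("entities", [])
        )
        relations = None
        if "relations" in extra:
            relations = {
                frozenset((r["e1"], r["e2"])): r["label"] for r in extra["relations"]
            }
        did = str(extra.get("doc_id", doc_id))
        if did not in by_doc:
            docs_order.append(did)
            by_doc[did] = []
        by_doc[did].append(
            ParsedSentence(sid, tuple(cur_tokens), tuple(cur_arcs), (), ents, relations)
        )
        cur_tokens, cur_arcs, sent_id = [], [], None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                if line.startswith("# sent_id"):
                    sent_id = line.split("=", 1)[1].strip()
                elif line.startswith("# newdoc id"):
                    doc_id = line.split("=", 1)[1].strip()
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise CorpusParseError(f"{path}: line {lineno}: expected 10 columns, got {len(cols)}")
            if "-" in cols[0] or "." in cols[0]:
                continue  # multiword-token / empty-node lines carry no tree structure
            try:
                idx = int(cols[0])
                head = int(cols[6]) if cols[6] != "_" else 0
            except ValueError as exc:
                raise CorpusParseError(f"{path}: line {lineno}: {exc}") from exc
            lemma = cols[2] if cols[2] != "_" else cols[1]
            pos = cols[4] if cols[4] != "_" else cols[3]
            cur_tokens.append(Token(idx, cols[1], lemma, pos))
            cur_arcs.append(DependencyArc(head, idx, cols[7]))
    flush()
    return [AnnotatedDocument(d, tuple(by_doc[d])) for d in docs_order]


def read_corpus(
    path: str | Path, fmt: str = "jsonl", sidecar: str | Path | None = None
) -> list[AnnotatedDocument]:
    """Read an annotated corpus; ``fmt`` is ``jsonl`` or ``conllu``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "jsonl":
        return _read_jsonl(path)
    if fmt == "conllu":
        return _read_conllu(path, Path(sidecar) if sidecar else None)
    raise ValueError(f"unknown corpus format {fmt!r}")


def write_corpus(docs: Iterable[AnnotatedDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            for sent in doc.sentences:
                fh.write(json.dumps(_record_from_sentence(doc.doc_id, sent)) + "\n")


# ---------------------------------------------------------------------------
# Candidate pairs & entity blinding
# ---------------------------------------------------------------------------

def enumerate_candidate_pairs(
    sentence: ParsedSentence, doc_id: str
) -> list[CandidatePairInstance]:
    """All unordered drug pairs co-occurring in the sentence.

    Pairs whose two mentions have identical (case-folded) names are removed;
    ``e1`` is the leftmost mention, and pairs are ordered by token position.
    """
    drugs = sorted(
        (e for e in sentence.entities if e.etype == "drug"),
        key=lambda e: (e.start_tok, e.id),
    )
    pairs: list[CandidatePairInstance] = []
    for i in range(len(drugs)):
        for j in range(i + 1, len(drugs)):
            a, b = drugs[i], drugs[j]
            if a.name.casefold() == b.name.casefold():
                continue
            label = None
            if sentence.relations is not None:
                label = sentence.relations.get(frozenset((a.id, b.id)), NDDI)
            pairs.append(
                CandidatePairInstance(doc_id, sentence.sentence_id, a.id, b.id, label)
            )
    return pairs


def span_head_token(sentence: ParsedSentence, ent: EntityMention) -> int:
    """Syntactic head of a mention span: the token whose dependency head lies
    outside the span (fallback: the span's last token)."""
    span = set(ent.token_span)
    for idx in ent.token_span:
        head = sentence.dep_head_of(idx)
        if head is None or head not in span:
            return idx
    return ent.end_tok


def blind_entities(
    sentence: ParsedSentence, pair: CandidatePairInstance
) -> ParsedSentence:
    """Replace the candidate pair's names with ``drug1``/``drug2`` and any other
    drug mention with the generic ``drug``.

    For multi-token mentions the span's syntactic head token carries the
    placeholder; the remaining span tokens are recorded in ``hidden_tokens`` so
    graph construction drops them. Parses are untouched. Idempotent.
    """
    ent1 = sentence.entity(pair.e1)
    ent2 = sentence.entity(pair.e2)
    if ent1.start_tok > ent2.start_tok:
        ent1, ent2 = ent2, ent1
    replacements: dict[int, str] = {}
    hidden: set[int] = set(sentence.hidden_tokens)
    for ent, placeholder in [(ent1, "drug1"), (ent2, "drug2")] + [
        (e, "drug")
        for e in sentence.entities
        if e.etype == "drug" and e.id not in (ent1.id, ent2.id)
    ]:
        head = span_head_token(sentence, ent)
        replacements[head] = placeholder
        hidden.update(i for i in ent.token_span if i != head)
    new_tokens = tuple(
        replace(t, surface=replacements[t.index], lemma=replacements[t.index])
        if t.index in replacements
        else t
        for t in sentence.tokens
    )
    return replace(sentence, tokens=new_tokens, hidden_tokens=frozenset(hidden))
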