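"""Semantic-class tagging and its integration into pair graphs.

Pharmacokinetic DDI text uses a narrow sublanguage: a small set of semantic
classes (Drug, Enzyme, PK parameter, Number, Mechanism, Change, Degree,
Negation) covers most interaction-relevant vocabulary.  Tagging tokens with
these classes and substituting the class name for the lemma label inside a
PairGraph collapses surface variation ("inhibit", "suppress", "block" all
become Mechanism), densifying the otherwise sparse lexical path features.

The Mechanism class can be refined into three mechanism subclasses:
Drug-enzyme (a drug acting on an enzyme, e.g. "inhibit"), Enzyme-drug (an
enzyme acting on a drug, e.g. "catalyze") and Drug-metabolite (conversion of
a drug to a metabolite, e.g. "hydroxylation").

Lexicons are plain text, one term per line, in a directory laid out as
``lexicon/<class>.txt`` + ``lexicon/number.regex`` +
``lexicon/mechanism_refined/<subclass>.txt``.  A small illustrative default
lexicon ships with the package.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .corpus_io import ParsedSentence
from .graphs import PairGraph, POSITION_SUFFIXES

logger = logging.getLogger(__name__)

__all__ = [
    "SemanticLexicon",
    "load_lexicon",
    "default_lexicon",
    "empty_lexicon",
    "annotate_tokens",
    "apply_semantic_classes",
    "CLASS_NAMES",
    "REFINED_CLASSES",
]

CLASS_NAMES = (
    "Drug",
    "Enzyme",
    "PK parameter",
    "Number",
    "Mechanism",
    "Change",
    "Degree",
    "Negation",
)
REFINED_CLASSES = ("Drug-enzyme", "Enzyme-drug", "Drug-metabolite")

# rarer / stronger cues win on multi-match
_PRECEDENCE = (
    "Negation",
    "Mechanism",
    "Change",
    "Degree",
    "PK parameter",
    "Enzyme",
    "Drug",
    "Number",
)

_FILE_NAMES = {
    "Drug": "drug.txt",
    "Enzyme": "enzyme.txt",
    "PK parameter": "pk_parameter.txt",
    "Number": "number.txt",
    "Mechanism": "mechanism.txt",
    "Change": "change.txt",
    "Degree": "degree.txt",
    "Negation": "negation.txt",
}
_REFINED_FILE_NAMES = {
    "Drug-enzyme": "drug_enzyme.txt",
    "Enzyme-drug": "enzyme_drug.txt",
    "Drug-metabolite": "drug_metabolite.txt",
}


@dataclass(frozen=True)
class SemanticLexicon:
    classes: dict = field(default_factory=dict)  # class name -> frozenset of terms
    regex_classes: dict = field(default_factory=dict)  # class name -> tuple of patterns
    mechanism_refined: dict = field(default_factory=dict)  # subclass -> frozenset

    def __post_init__(self) -> None:
        mech = self.classes.get("Mechanism", frozenset())
        for sub, terms in self.mechanism_refined.items():
            extra = terms - mech
            if extra:
                raise ValueError(
                    f"refined mechanism class {sub!r} contains terms absent from "
                    f"the Mechanism class: {sorted(extra)[:5]}"
                )

    def is_empty(self) -> bool:
        return not any(self.classes.values()) and not any(self.regex_classes.values())


def empty_lexicon() -> SemanticLexicon:
    return SemanticLexicon({name: frozenset() for name in CLASS_NAMES}, {}, {})


def _read_terms(path: Path) -> frozenset:
    if not path.exists():
        return frozenset()
    terms = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        term = line.strip().casefold()
        if term and not term.startswith("#"):
            terms.add(term)
    return frozenset(terms)


def load_lexicon(directory: str | Path) -> SemanticLexicon:
    """Load a lexicon directory (missing class files yield empty classes)."""
    directory = Path(directory)
    classes = {
        name: _read_terms(directory / fname) for name, fname in _FILE_NAMES.items()
    }
    regex_classes = {}
    regex_path = directory / "number.regex"
    if regex_path.exists():
        patterns = tuple(
            re.compile(line.strip())
            for line in regex_path.read_text(encoding="utf-8").splitlines()
            if line.strip() and not line.startswith("#")
        )
        regex_classes["Number"] = patterns
    refined = {
        sub: _read_terms(directory / "mechanism_refined" / fname)
        for sub, fname in _REFINED_FILE_NAMES.items()
    }
    refined = {sub: terms for sub, terms in refined.items() if terms}
    return SemanticLexicon(classes, regex_classes, refined)


def default_lexicon() -> SemanticLexicon:
    """The small illustrative lexicon shipped with the package."""
    root = resources.files("ddikernel") / "data" / "lexicon"
    with resources.as_file(root) as path:
        return load_lexicon(path)


def _head_of_ngram(sentence: ParsedSentence, span: range) -> int:
    # tokens whose dependency head lies outside the span; unique in a tree,
    # and the rightmost candidate is the conventional head when unparsed
    span_set = set(span)
    candidates = [
        idx for idx in span
        if (head := sentence.dep_head_of(idx)) is None or head not in span_set
    ]
    return candidates[-1] if candidates else span[-1]


def annotate_tokens(
    sentence: ParsedSentence, lexicon: SemanticLexicon, refined: bool = False
) -> dict:
    """Tag tokens with semantic classes; returns {token index -> class name}.

    Matching is case-insensitive on lemmas (fallback: surface).  Multiword
    triggers are matched longest-first over lemma n-grams up to length 4, the
    tag landing on the n-gram's syntactic head token.  The Number class is
    additionally matched by regex on the surface form.  With ``refined``,
    Mechanism hits are re-labelled by the refined sub-lexicons (falling back
    to coarse Mechanism when no subclass covers the term).  Generic blinded
    ``drug`` mentions are tagged Drug; the drug1/drug2 pair anchors are left
    untouched so the pair stays identifiable after substitution.
    """
    tagging: dict[int, str] = {}
    consumed: set[int] = set()
    tokens = [t for t in sentence.tokens if t.index not in sentence.hidden_tokens]
    lemmas = {t.index: (t.lemma or t.surface).casefold() for t in tokens}

    def class_of(term: str) -> str | None:
        for cname in _PRECEDENCE:
            if term in lexicon.classes.get(cname, frozenset()):
                if cname == "Mechanism" and refined:
                    for sub in REFINED_CLASSES:
                        if term in lexicon.mechanism_refined.get(sub, frozenset()):
                            return sub
                    logger.debug("Mechanism term %r has no refined subclass", term)
                return cname
        return None

    # multiword triggers, longest match first
    indices = [t.index for t in tokens]
    for n in range(4, 1, -1):
        for start in range(len(indices) - n + 1):
            span_idx = indices[start : start + n]
            if any(i in consumed for i in span_idx):
                continue
            term = " ".join(lemmas[i] for i in span_idx)
            cname = class_of(term)
            if cname is not None:
                head = _head_of_ngram(sentence, range(span_idx[0], span_idx[-1] + 1))
                if head not in span_idx:
                    head = span_idx[-1]
                tagging[head] = cname
                consumed.update(span_idx)

    lexicon_active = not lexicon.is_empty()
    for tok in tokens:
        if tok.index in consumed:
            continue
        lemma = lemmas[tok.index]
        if lemma in ("drug1", "drug2"):
            # the pair anchors keep their placeholder labels: substituting
            # both with "Drug" would erase which vertex is which
            continue
        if lemma == "drug" and lexicon_active:
            tagging[tok.index] = "Drug"
            continue
        cname = class_of(lemma)
        if cname is None:
            for pattern in lexicon.regex_classes.get("Number", ()):
                if pattern.fullmatch(tok.surface) or pattern.fullmatch(lemma):
                    cname = "Number"
                    break
        if cname is not None:
            tagging[tok.index] = cname
    return tagging


def _substitute(label: str, class_name: str) -> str:
    """Replace the lexical part of a label, preserving any position suffix."""
    for suffix in POSITION_SUFFIXES:
        if label.endswith("_" + suffix):
            return f"{class_name}_{suffix}"
    return class_name


def apply_semantic_classes(graph: PairGraph, tagging: dict) -> PairGraph:
    """Replace the lemma label of every tagged token's word vertices (both
    components) with its semantic-class name, keeping position suffixes and
    POS labels; relation vertices, edges and weights are untouched."""
    out = graph.copy()
    for v in out.vertices:
        if v.kind != "word" or v.token_index not in tagging:
            continue
        class_name = tagging[v.token_index]
        # by construction the first label is the lemma-derived one
        v.labels[0] = _substitute(v.labels[0], class_name)
    return out
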