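"""Seeded generator of pre-parsed synthetic PK-DDI corpora.

Real PK-DDI corpora are documents of sentences with drug mentions, candidate
pairs labelled DDI/NDDI, dependency parses, PAS arcs, and a sublanguage of
trigger words (mechanism verbs, PK-parameter changes, degree adverbs,
negations).  This module emulates that structure with hand-authored sentence
templates, each carrying its own dependency tree and PAS arcs, so every
pipeline stage runs without any external parser or download.

The label signal mirrors the linguistic mechanism the kernel method relies
on: a pair is positive exactly when a Mechanism/Change trigger lies on the
dependency path between the two drugs.  Negative patterns include a
structural twin of the positive templates with a non-trigger verb,
conjunction lists, negated triggers, and mere co-occurrence.  Triggers are
sampled from class-specific synonym pools, so lexical path features are
sparse while semantic-class features are dense — the contrast the
semantic-class integration is designed to exploit.  "Clausal" sentences
compose two clauses under a subordinating conjunction, emulating the long
multi-clause sentences of in-vitro study reports; their cross-clause drug
pairs are negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import (
    AnnotatedDocument,
    DependencyArc,
    EntityMention,
    ParsedSentence,
    PasArc,
    Token,
)
from .graphs import PairGraph, Vertex, WeightedEdge
from .semantics import SemanticLexicon

DDI = "DDI"
NDDI = "NDDI"

__all__ = [
    "GeneratorConfig",
    "generate_corpus",
    "generate_random_pair_graph",
    "DRUG_NAMES",
]

# --------------------------------------------------------------------------
# Synonym pools (truncated to synonym_pool_size per trigger class)
# --------------------------------------------------------------------------

CHANGE_VERBS = [
    "increase", "decrease", "elevate", "reduce", "augment", "diminish",
    "raise", "lower", "boost", "attenuate", "amplify", "curtail",
]
DRUG_ENZYME_VERBS = [
    "inhibit", "induce", "inactivate", "block", "suppress", "stimulate",
    "potentiate", "antagonize", "repress", "impede",
]
ENZYME_DRUG_VERBS = [
    "catalyze", "metabolize", "oxidize", "demethylate", "hydroxylate",
    "deacetylate", "conjugate", "cleave", "biotransform", "degrade",
]
METABOLITE_NOUNS = [
    "hydroxylation", "demethylation", "oxidation", "glucuronidation",
    "deacetylation", "dealkylation", "methylation", "sulfation",
    "acetylation", "nitration",
]
# Non-trigger vocabulary is an open class in real text, so these pools are
# deliberately large and independent of the trigger synonym-pool size.
NEUTRAL_VERBS = [
    "accompany", "follow", "precede", "concern", "involve", "represent",
    "parallel", "resemble", "approximate", "mirror", "match", "reflect",
    "track", "predict", "characterize", "describe", "summarize", "illustrate",
    "indicate", "denote", "record", "document", "display", "show", "reveal",
    "confirm", "support", "corroborate", "complement", "overlap", "join",
    "bracket",
]
NEUTRAL_NOUNS = [
    "measurement", "assessment", "observation", "profile", "course",
    "distribution", "comparison", "monitoring", "evaluation", "record",
    "summary", "overview", "description", "analysis", "review", "report",
    "history", "timeline", "baseline", "pattern", "trend", "average",
    "variability", "range",
]
FILLER_NOUNS = [
    "patients", "volunteers", "subjects", "microsomes", "hepatocytes",
    "rats", "dogs", "humans", "plasma", "serum", "urine", "blood",
    "adults", "children", "smokers", "men", "women", "donors",
    "cultures", "assays", "cells", "tissue", "liver", "kidney",
]
TIME_NOUNS = [
    "treatment", "dosing", "coadministration", "pretreatment", "washout",
    "fasting", "infusion", "induction", "incubation", "titration",
    "randomization", "screening",
]
PK_PARAMS = [
    "auc", "clearance", "half-life", "cmax", "tmax", "bioavailability",
    "exposure", "concentration", "absorption", "elimination",
]
DEGREE_ADVS = [
    "markedly", "strongly", "significantly", "slightly", "modestly",
    "substantially", "greatly", "mildly", "moderately", "notably",
]
ENZYMES = [
    "cyp3a4", "cyp2d6", "cyp2c9", "cyp1a2", "cyp2c19", "cyp2b6", "cyp2e1",
    "cyp2a6", "ugt1a1", "fmo3",
]
NEGATIONS = ["not", "no"]

DRUG_NAMES = [
    prefix + suffix
    for prefix in ("alpra", "beta", "carvo", "dexi", "elora", "fluvo", "gemi", "halo")
    for suffix in ("zine", "folol", "micin", "pride", "xaban")
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults produce roughly 800 candidate pairs over 200 documents with a
    0.35 positive rate, 5% label noise and synonym pools of 8 terms per
    trigger class.
    """

    n_docs: int = 200
    sentences_per_doc: tuple = (1, 4)
    drugs_per_sentence: tuple = (2, 4)
    positive_rate: float = 0.35
    synonym_pool_size: int = 8
    label_noise_rate: float = 0.05
    clausal_rate: float = 0.10  # fraction of sentences composed of two clauses
    seed: int = 42

    def __post_init__(self) -> None:
        for rate in (self.positive_rate, self.label_noise_rate, self.clausal_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.synonym_pool_size < 1:
            raise ValueError("synonym pools must hold at least one term")


def _pool(base: list, size: int) -> list:
    """First ``size`` terms; overflow generates suffixed variants."""
    if size <= len(base):
        return base[:size]
    out = list(base)
    i = 2
    while len(out) < size:
        out.extend(f"{term}{i}" for term in base[: size - len(out)])
        i += 1
    return out[:size]


@dataclass
class _Pools:
    change: list
    drug_enzyme: list
    enzyme_drug: list
    metabolite: list
    neutral: list
    neutral_nouns: list
    fillers: list
    params: list
    degrees: list
    enzymes: list

    @classmethod
    def build(cls, size: int) -> "_Pools":
        return cls(
            change=_pool(CHANGE_VERBS, size),
            drug_enzyme=_pool(DRUG_ENZYME_VERBS, size),
            enzyme_drug=_pool(ENZYME_DRUG_VERBS, size),
            metabolite=_pool(METABOLITE_NOUNS, size),
            neutral=list(NEUTRAL_VERBS),
            neutral_nouns=list(NEUTRAL_NOUNS),
            fillers=list(FILLER_NOUNS),
            params=_pool(PK_PARAMS, size),
            degrees=_pool(DEGREE_ADVS, size),
            enzymes=_pool(ENZYMES, size),
        )

    def lexicon(self) -> SemanticLexicon:
        import re

        mechanism = frozenset(self.drug_enzyme) | frozenset(self.enzyme_drug) | frozenset(
            self.metabolite
        )
        return SemanticLexicon(
            classes={
                "Drug": frozenset(DRUG_NAMES),
                "Enzyme": frozenset(self.enzymes),
                "PK parameter": frozenset(self.params),
                "Number": frozenset(),
                "Mechanism": mechanism,
                "Change": frozenset(self.change),
                "Degree": frozenset(self.degrees),
                "Negation": frozenset(NEGATIONS),
            },
            regex_classes={
                "Number": (re.compile(r"[0-9]+(\.[0-9]+)?"), re.compile(r"%")),
            },
            mechanism_refined={
                "Drug-enzyme": frozenset(self.drug_enzyme),
                "Enzyme-drug": frozenset(self.enzyme_drug),
                "Drug-metabolite": frozenset(self.metabolite),
            },
        )


# --------------------------------------------------------------------------
# Sentence templates: hand-authored tokens + dependency tree + PAS arcs
# --------------------------------------------------------------------------

@dataclass
class _Clause:
    """One clause: tokens as (surface, lemma, pos), arcs with 1-based local
    indices, drug slot positions, root index, and per-pair label rule."""

    tokens: list
    dep: list  # (head, dependent, label)
    pas: list  # (pred, role, arg)
    drug_slots: list  # token indices holding drug mentions
    root: int
    positive: bool  # label of the within-clause drug pair(s)


def _clause_change_active(rng, pools: _Pools, positive: bool) -> _Clause:
    """drug1 [ADV] VERB the PARAM of drug2 [by NUM %]"""
    verb = rng.choice(pools.change + pools.drug_enzyme if positive else pools.neutral)
    param = rng.choice(pools.params)
    tokens = [("DRUG", "DRUG", "NN")]
    adv = rng.random() < 0.5
    if adv:
        tokens.append((rng.choice(pools.degrees),) * 2 + ("RB",))
    v = len(tokens) + 1
    tokens += [
        (verb + "s", verb, "VBZ"),
        ("the", "the", "DT"),
        (param, param, "NN"),
        ("of", "of", "IN"),
        ("DRUG", "DRUG", "NN"),
    ]
    p = v + 2  # PARAM index
    d2 = v + 4
    dep = [(0, v, "root"), (v, 1, "nsubj"), (v, p, "dobj"), (p, v + 1, "det"),
           (p, d2, "prep_of"), (p, v + 3, "prep")]
    if adv:
        dep.append((v, 2, "advmod"))
    pas = [(v, "ARG1", 1), (v, "ARG2", p), (v + 3, "ARG1", p), (v + 3, "ARG2", d2)]
    if rng.random() < 0.3:
        b = len(tokens) + 1
        num = str(rng.integers(10, 90))
        tokens += [("by", "by", "IN"), (num, num, "CD"), ("%", "%", "NN")]
        dep += [(v, b + 2, "prep_by"), (b + 2, b + 1, "num"), (v, b, "prep")]
        pas += [(b, "ARG1", v), (b, "ARG2", b + 2)]
    return _Clause(tokens, dep, pas, [1, d2], v, positive)


def _clause_mech_passive(rng, pools: _Pools, positive: bool) -> _Clause:
    """the PARAM of drug1 was VERB-ed by drug2"""
    verb = rng.choice(pools.change + pools.drug_enzyme if positive else pools.neutral)
    param = rng.choice(pools.params)
    tokens = [
        ("the", "the", "DT"),
        (param, param, "NN"),
        ("of", "of", "IN"),
        ("DRUG", "DRUG", "NN"),
        ("was", "be", "VBD"),
        (verb + "ed", verb, "VBN"),
        ("by", "by", "IN"),
        ("DRUG", "DRUG", "NN"),
    ]
    dep = [(0, 6, "root"), (6, 2, "nsubjpass"), (2, 1, "det"), (2, 4, "prep_of"),
           (2, 3, "prep"), (6, 5, "auxpass"), (6, 8, "agent"), (6, 7, "prep")]
    pas = [(6, "ARG2", 2), (6, "ARG1", 8), (3, "ARG1", 2), (3, "ARG2", 4)]
    return _Clause(tokens, dep, pas, [4, 8], 6, positive)


def _clause_enzyme_nominal(rng, pools: _Pools, positive: bool) -> _Clause:
    """drug1 VERB the ENZ -mediated METAB of drug2 (negative twin swaps both
    the verb and the nominal for neutral vocabulary, keeping the tree)"""
    verb = rng.choice(pools.drug_enzyme if positive else pools.neutral)
    enz = rng.choice(pools.enzymes)
    noun = rng.choice(pools.metabolite if positive else pools.neutral_nouns)
    tokens = [
        ("DRUG", "DRUG", "NN"),
        (verb + "s", verb, "VBZ"),
        ("the", "the", "DT"),
        (enz, enz, "NN"),
        ("mediated", "mediate", "VBN"),
        (noun, noun, "NN"),
        ("of", "of", "IN"),
        ("DRUG", "DRUG", "NN"),
    ]
    dep = [(0, 2, "root"), (2, 1, "nsubj"), (2, 6, "dobj"), (6, 3, "det"),
           (6, 4, "nn"), (6, 5, "amod"), (6, 8, "prep_of"), (6, 7, "prep")]
    pas = [(2, "ARG1", 1), (2, "ARG2", 6), (5, "ARG1", 4), (5, "ARG2", 6),
           (7, "ARG1", 6), (7, "ARG2", 8)]
    return _Clause(tokens, dep, pas, [1, 8], 2, positive)


def _clause_nominalization(rng, pools: _Pools, positive: bool) -> _Clause:
    """the NOUN of drug1 by drug2 was observed — the trigger is a mechanism
    nominal sitting between the two prepositional drug attachments"""
    noun = rng.choice(pools.metabolite if positive else pools.neutral_nouns)
    tokens = [
        ("the", "the", "DT"),
        (noun, noun, "NN"),
        ("of", "of", "IN"),
        ("DRUG", "DRUG", "NN"),
        ("by", "by", "IN"),
        ("DRUG", "DRUG", "NN"),
        ("was", "be", "VBD"),
        ("observed", "observe", "VBN"),
    ]
    dep = [(0, 8, "root"), (8, 2, "nsubjpass"), (2, 1, "det"), (2, 4, "prep_of"),
           (2, 3, "prep"), (2, 6, "prep_by"), (2, 5, "prep"), (8, 7, "auxpass")]
    pas = [(8, "ARG2", 2), (3, "ARG1", 2), (3, "ARG2", 4),
           (5, "ARG1", 2), (5, "ARG2", 6)]
    return _Clause(tokens, dep, pas, [4, 6], 8, positive)


def _clause_relative(rng, pools: _Pools, positive: bool) -> _Clause:
    """drug1 VERB1 the ENZ that VERB2 drug2 — two trigger lemmas on the path"""
    if positive:
        v1 = rng.choice(pools.drug_enzyme)
        v2 = rng.choice(pools.enzyme_drug)
    else:
        v1, v2 = rng.choice(pools.neutral, size=2)
    enz = rng.choice(pools.enzymes)
    tokens = [
        ("DRUG", "DRUG", "NN"),
        (v1 + "s", v1, "VBZ"),
        ("the", "the", "DT"),
        (enz, enz, "NN"),
        ("that", "that", "WDT"),
        (v2 + "s", v2, "VBZ"),
        ("DRUG", "DRUG", "NN"),
    ]
    dep = [(0, 2, "root"), (2, 1, "nsubj"), (2, 4, "dobj"), (4, 3, "det"),
           (4, 6, "rcmod"), (6, 5, "nsubj"), (6, 7, "dobj")]
    pas = [(2, "ARG1", 1), (2, "ARG2", 4), (6, "ARG1", 4), (6, "ARG2", 7)]
    return _Clause(tokens, dep, pas, [1, 7], 2, positive)


def _with_filler(clause: _Clause, rng, pools: _Pools) -> _Clause:
    """Append a variable amount of non-discriminative adjunct material to the
    clause root: 'in <cohort>', 'after <event>' and a parenthetical P-value.
    Real sentences carry plenty of such content; it dilutes kernel similarity
    without carrying label signal."""
    def pp(prep: str, noun: str) -> None:
        i = len(clause.tokens) + 1
        clause.tokens += [(prep, prep, "IN"), (noun, noun, "NN")]
        clause.dep += [(clause.root, i + 1, f"prep_{prep}"), (clause.root, i, "prep")]
        clause.pas += [(i, "ARG1", clause.root), (i, "ARG2", i + 1)]

    if rng.random() < 0.6:
        pp("in", rng.choice(pools.fillers))
    if rng.random() < 0.4:
        pp("after", rng.choice(TIME_NOUNS))
    if rng.random() < 0.4:
        i = len(clause.tokens) + 1
        num = "0.0" + str(rng.integers(1, 10))
        clause.tokens += [("(", "(", "-LRB-"), ("P", "p", "NN"), ("<", "<", "SYM"),
                          (num, num, "CD"), (")", ")", "-RRB-")]
        clause.dep += [(clause.root, i + 3, "parataxis"), (i + 3, i, "punct"),
                       (i + 3, i + 1, "nsubj"), (i + 3, i + 2, "punct2"),
                       (i + 3, i + 4, "punct")]
    return clause


def _clause_negation(rng, pools: _Pools) -> _Clause:
    """drug1 did not VERB the PARAM of drug2 — trigger on path, label NDDI"""
    verb = rng.choice(pools.change + pools.drug_enzyme)
    param = rng.choice(pools.params)
    tokens = [
        ("DRUG", "DRUG", "NN"),
        ("did", "do", "VBD"),
        ("not", "not", "RB"),
        (verb, verb, "VB"),
        ("the", "the", "DT"),
        (param, param, "NN"),
        ("of", "of", "IN"),
        ("DRUG", "DRUG", "NN"),
    ]
    dep = [(0, 4, "root"), (4, 1, "nsubj"), (4, 2, "aux"), (4, 3, "neg"),
           (4, 6, "dobj"), (6, 5, "det"), (6, 8, "prep_of"), (6, 7, "prep")]
    pas = [(4, "ARG1", 1), (4, "ARG2", 6), (3, "ARG1", 4),
           (7, "ARG1", 6), (7, "ARG2", 8)]
    return _Clause(tokens, dep, pas, [1, 8], 4, False)


def _clause_cooccurrence(rng, pools: _Pools) -> _Clause:
    """the PARAM of drug1 and the PARAM of drug2 were measured"""
    p1, p2 = rng.choice(pools.params, size=2)
    tokens = [
        ("the", "the", "DT"), (p1, p1, "NN"), ("of", "of", "IN"),
        ("DRUG", "DRUG", "NN"), ("and", "and", "CC"), ("the", "the", "DT"),
        (p2, p2, "NN"), ("of", "of", "IN"), ("DRUG", "DRUG", "NN"),
        ("were", "be", "VBD"), ("measured", "measure", "VBN"),
    ]
    dep = [(0, 11, "root"), (11, 2, "nsubjpass"), (2, 1, "det"), (2, 4, "prep_of"),
           (2, 3, "prep"), (2, 5, "cc"), (2, 7, "conj_and"), (7, 6, "det"),
           (7, 9, "prep_of"), (7, 8, "prep"), (11, 10, "auxpass")]
    pas = [(11, "ARG2", 2), (3, "ARG1", 2), (3, "ARG2", 4),
           (8, "ARG1", 7), (8, "ARG2", 9), (5, "ARG1", 2), (5, "ARG2", 7)]
    return _Clause(tokens, dep, pas, [4, 9], 11, False)


def _clause_conj_list(rng, pools: _Pools) -> _Clause:
    """drug1 , drug2 and drug3 were administered to patients (3 drugs)"""
    tokens = [
        ("DRUG", "DRUG", "NN"), (",", ",", ","), ("DRUG", "DRUG", "NN"),
        ("and", "and", "CC"), ("DRUG", "DRUG", "NN"), ("were", "be", "VBD"),
        ("administered", "administer", "VBN"), ("to", "to", "IN"),
        ("patients", "patient", "NNS"),
    ]
    dep = [(0, 7, "root"), (7, 1, "nsubjpass"), (1, 2, "punct"), (1, 3, "conj_and"),
           (1, 4, "cc"), (1, 5, "conj_and"), (7, 6, "auxpass"), (7, 9, "prep_to"),
           (7, 8, "prep")]
    pas = [(7, "ARG2", 1), (4, "ARG1", 1), (4, "ARG2", 3), (4, "ARG2", 5),
           (8, "ARG1", 7), (8, "ARG2", 9)]
    return _Clause(tokens, dep, pas, [1, 3, 5], 7, False)


# positive templates and their structural negative twins share the builders;
# the twin keeps the parse and swaps trigger vocabulary for neutral words
_TWIN_BUILDERS = (
    _clause_change_active,
    _clause_mech_passive,
    _clause_enzyme_nominal,
    _clause_nominalization,
    _clause_relative,
)

# Structure-matched twins are the hard negatives the method is about, so they
# make up half of the negative patterns; the remaining mass is split over the
# negation / co-occurrence / conjunction-list patterns.
def _negative_kinds(max_drugs: int) -> tuple:
    if max_drugs >= 3:
        return ("twin", "negation", "cooc", "conj"), (0.5, 1 / 6, 1 / 6, 1 / 6)
    return ("twin", "negation", "cooc"), (0.5, 0.25, 0.25)


def _mean_negative_pairs(max_drugs: int) -> float:
    kinds, probs = _negative_kinds(max_drugs)
    pairs = {"twin": 1.0, "negation": 1.0, "cooc": 1.0, "conj": 3.0}
    return sum(p * pairs[k] for k, p in zip(kinds, probs))


def _simple_clause(rng, pools: _Pools, positive: bool, max_drugs: int) -> _Clause:
    if positive:
        builder = _TWIN_BUILDERS[rng.integers(len(_TWIN_BUILDERS))]
        return _with_filler(builder(rng, pools, True), rng, pools)
    kinds, probs = _negative_kinds(max_drugs)
    kind = kinds[rng.choice(len(kinds), p=probs)]
    if kind == "twin":
        clause = _TWIN_BUILDERS[rng.integers(len(_TWIN_BUILDERS))](rng, pools, False)
    elif kind == "negation":
        clause = _clause_negation(rng, pools)
    elif kind == "conj":
        clause = _clause_conj_list(rng, pools)
    else:
        clause = _clause_cooccurrence(rng, pools)
    return _with_filler(clause, rng, pools)


def _offset_clause(clause: _Clause, offset: int) -> _Clause:
    return _Clause(
        tokens=list(clause.tokens),
        dep=[(h + offset if h else 0, d + offset, lab) for h, d, lab in clause.dep],
        pas=[(p + offset, r, a + offset) for p, r, a in clause.pas],
        drug_slots=[s + offset for s in clause.drug_slots],
        root=clause.root + offset,
        positive=clause.positive,
    )


def _compose_sentence(
    rng, clauses: list, sentence_id: str, drug_names: list
) -> tuple[ParsedSentence, dict]:
    """Join clauses with ', whereas' and close with '.'; returns the sentence
    and its gold relations (within-clause per rule, cross-clause NDDI)."""
    tokens: list = []
    dep: list = []
    pas: list = []
    placed: list[_Clause] = []
    for k, clause in enumerate(clauses):
        if k > 0:
            conj = "whereas" if rng.random() < 0.5 else "while"
            tokens.append((",", ",", ","))
            tokens.append((conj, conj, "IN"))
            conj_idx = len(tokens)
        off = len(tokens)
        shifted = _offset_clause(clause, off)
        tokens.extend(clause.tokens)
        if k == 0:
            dep.extend(shifted.dep)
        else:
            first_root = placed[0].root
            for h, d, lab in shifted.dep:
                dep.append((first_root if h == 0 else h, d, "advcl" if h == 0 else lab))
            dep.append((shifted.root, conj_idx, "mark"))
            dep.append((shifted.root, conj_idx - 1, "punct"))
        pas.extend(shifted.pas)
        placed.append(shifted)
    tokens.append((".", ".", "."))
    dep.append((placed[0].root, len(tokens), "punct"))

    # fill drug slots with distinct names
    all_slots = [s for c in placed for s in c.drug_slots]
    names = rng.choice(len(drug_names), size=len(all_slots), replace=False)
    name_at = {slot: drug_names[i] for slot, i in zip(all_slots, names)}
    final_tokens = []
    for i, (surface, lemma, pos) in enumerate(tokens, start=1):
        if i in name_at:
            final_tokens.append(Token(i, name_at[i], name_at[i], pos))
        else:
            final_tokens.append(Token(i, surface, lemma, pos))

    entities = tuple(
        EntityMention(f"{sentence_id}_e{j}", slot, slot, "drug", name_at[slot])
        for j, slot in enumerate(sorted(all_slots), start=1)
    )
    ent_at = {e.start_tok: e.id for e in entities}
    relations: dict = {}
    for c in placed:
        slots = c.drug_slots
        for i in range(len(slots)):
            for j in range(i + 1, len(slots)):
                relations[frozenset((ent_at[slots[i]], ent_at[slots[j]]))] = (
                    DDI if c.positive else NDDI
                )
    # cross-clause pairs are negative
    for a in range(len(placed)):
        for b in range(a + 1, len(placed)):
            for si in placed[a].drug_slots:
                for sj in placed[b].drug_slots:
                    relations[frozenset((ent_at[si], ent_at[sj]))] = NDDI

    sent = ParsedSentence(
        sentence_id=sentence_id,
        tokens=tuple(final_tokens),
        dep_arcs=tuple(DependencyArc(h, d, lab) for h, d, lab in dep),
        pas_arcs=tuple(PasArc(p, r, a) for p, r, a in pas),
        entities=entities,
        relations=relations,
    )
    return sent, relations


def generate_corpus(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[list, SemanticLexicon]:
    """Generate a corpus of AnnotatedDocuments plus the matching lexicon.

    Deterministic for a given config (byte-identical on repeated calls).
    Labels follow the template rules and are then flipped independently with
    probability ``label_noise_rate``.
    """
    rng = np.random.default_rng(config.seed)
    pools = _Pools.build(config.synonym_pool_size)
    lexicon = pools.lexicon()
    min_s, max_s = config.sentences_per_doc
    max_drugs = config.drugs_per_sentence[1]
    clausal_ok = max_drugs >= 4
    # Solve the sentence-level positive probability so the expected
    # *pair-level* positive fraction (before label noise) hits the target:
    # negative patterns can contribute several pairs per sentence (the
    # conjunction list) and two-clause sentences always contribute four
    # negative cross-clause pairs.
    r = config.positive_rate
    c = config.clausal_rate if clausal_ok else 0.0
    q_clausal = min(1.0, 3.0 * r)
    e_neg = _mean_negative_pairs(max_drugs)
    den = (1.0 - c) * (1.0 - r * (1.0 - e_neg))
    num = r * (1.0 - c) * e_neg + 6.0 * r * c - 2.0 * c * q_clausal
    p_sentence = min(1.0, max(0.0, num / den)) if den > 0 else r

    docs = []
    for d in range(config.n_docs):
        doc_id = f"d{d:04d}"
        n_sent = int(rng.integers(min_s, max_s + 1))
        sentences = []
        for s in range(n_sent):
            sid = f"{doc_id}_s{s}"
            clausal = clausal_ok and rng.random() < config.clausal_rate
            if clausal:
                clauses = [
                    _simple_clause(rng, pools, rng.random() < q_clausal, 2)
                    for _ in range(2)
                ]
            else:
                positive = rng.random() < p_sentence
                clauses = [_simple_clause(rng, pools, positive, max_drugs)]
            sent, relations = _compose_sentence(rng, clauses, sid, DRUG_NAMES)
            if config.label_noise_rate > 0:
                noisy = dict(relations)
                for key, label in relations.items():
                    if rng.random() < config.label_noise_rate:
                        noisy[key] = NDDI if label == DDI else DDI
                sent = ParsedSentence(
                    sent.sentence_id, sent.tokens, sent.dep_arcs, sent.pas_arcs,
                    sent.entities, noisy,
                )
            sentences.append(sent)
        docs.append(AnnotatedDocument(doc_id, tuple(sentences)))
    return docs, lexicon


# --------------------------------------------------------------------------
# Random graphs for kernel property tests
# --------------------------------------------------------------------------

def generate_random_pair_graph(
    n_vertices: int,
    edge_prob: float,
    acyclic: bool = True,
    seed: int = 0,
    weights: tuple = (0.3, 0.9),
    target_rho: float | None = None,
) -> PairGraph:
    """Random labelled weighted graph with designated drug1/drug2 vertices.

    With ``acyclic`` all edges point from lower to higher vertex index, so the
    adjacency matrix is nilpotent and the Neumann series is finite.  Without
    it, edges may run both ways (a 2-cycle between the two drug vertices is
    always inserted) and edge weights are rescaled so the spectral radius is
    ``target_rho`` (default: at most 0.7, where a 60-term truncation of the
    series is accurate far beyond 1e-6).
    """
    if n_vertices < 2:
        raise ValueError("need at least drug1 and drug2 vertices")
    rng = np.random.default_rng(seed)
    vertices = [
        Vertex(0, "word", ["drug1"]),
        Vertex(1, "word", ["drug2"]),
    ]
    label_pool = [f"w{i}" for i in range(8)]
    for vid in range(2, n_vertices):
        k = int(rng.integers(1, 3))
        labs = list(rng.choice(label_pool, size=k, replace=False))
        vertices.append(Vertex(vid, "word", labs))

    edges = []
    seen = set()

    def add(i: int, j: int) -> None:
        if i != j and (i, j) not in seen:
            seen.add((i, j))
            edges.append(WeightedEdge(i, j, float(rng.choice(weights))))

    for i in range(n_vertices):
        for j in range(n_vertices):
            if i == j:
                continue
            if acyclic and i >= j:
                continue
            if rng.random() < edge_prob:
                add(i, j)
    if not acyclic:
        add(0, 1)
        add(1, 0)

    if not acyclic:
        A = np.zeros((n_vertices, n_vertices))
        for e in edges:
            A[e.src, e.dst] = e.weight
        rho = float(np.max(np.abs(np.linalg.eigvals(A))))
        goal = target_rho if target_rho is not None else min(0.7, rho)
        if rho > 0:
            scale = goal / rho
            edges = [WeightedEdge(e.src, e.dst, e.weight * scale) for e in edges]

    return PairGraph(vertices, edges, {"structure": (0, 1)})
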