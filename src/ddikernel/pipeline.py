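"""End-to-end experiment orchestration for the six method variants.

A method variant pairs a structure representation (DEP: dependency graph,
PAS: predicate-argument graph) with a semantic-class option (none, SC:
coarse classes, ReSC: refined Mechanism subclasses), giving DEP, PAS,
DEP_SC, PAS_SC, DEP_ReSC and PAS_ReSC.

For each variant the pipeline blinds each candidate pair's sentence, builds
the pair graph, optionally substitutes semantic classes, derives the label
vocabulary from training graphs only, computes Gram matrices, picks the
decision threshold by leave-one-document-out cross-validation on the
training set, refits on all training data, scores the test set and reports
precision/recall/F1, ROC/AUC and per-document F1 for paired significance
tests against the DEP and PAS baselines.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import evaluation, rls
from .corpus_io import CandidatePairInstance, ParsedSentence, blind_entities, enumerate_candidate_pairs
from .graphs import EdgeWeightPolicy, build_pair_graph
from .kernel import (
    LabelVocabulary,
    build_label_vocabulary,
    cross_gram_matrix,
    feature_matrix_rows,
)
from .semantics import SemanticLexicon, annotate_tokens, apply_semantic_classes

logger = logging.getLogger(__name__)

DDI = "DDI"
NDDI = "NDDI"

METHOD_NAMES = ("DEP", "PAS", "DEP_SC", "PAS_SC", "DEP_ReSC", "PAS_ReSC")

__all__ = [
    "MethodSpec",
    "ExperimentConfig",
    "MethodResult",
    "ExperimentResult",
    "Instance",
    "collect_instances",
    "build_graphs",
    "run_experiment",
    "train_model",
    "predict",
    "METHOD_NAMES",
]


@dataclass(frozen=True)
class MethodSpec:
    structure: str  # DEP | PAS
    classes: str = "none"  # none | SC | ReSC

    def __post_init__(self) -> None:
        if self.structure not in ("DEP", "PAS"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.classes not in ("none", "SC", "ReSC"):
            raise ValueError(f"unknown semantic-class option {self.classes!r}")

    @property
    def name(self) -> str:
        return self.structure if self.classes == "none" else f"{self.structure}_{self.classes}"

    @classmethod
    def parse(cls, name: str) -> "MethodSpec":
        parts = name.split("_", 1)
        classes = {"sc": "SC", "resc": "ReSC", "none": "none"}.get(
            parts[1].lower() if len(parts) > 1 else "none"
        )
        if classes is None:
            raise ValueError(f"unknown method name {name!r}")
        return cls(parts[0].upper(), classes)


@dataclass(frozen=True)
class ExperimentConfig:
    lam: float = rls.DEFAULT_LAMBDA
    n_basis: int = 500
    seed: int = 0
    policy: EdgeWeightPolicy = field(default_factory=EdgeWeightPolicy)


@dataclass
class Instance:
    doc_id: str
    sentence: ParsedSentence
    pair: CandidatePairInstance


def collect_instances(docs) -> list:
    """Flatten documents into candidate-pair instances (document order kept)."""
    instances = []
    for doc in docs:
        for sent in doc.sentences:
            for pair in enumerate_candidate_pairs(sent, doc.doc_id):
                instances.append(Instance(doc.doc_id, sent, pair))
    return instances


def build_graphs(
    instances,
    method: MethodSpec,
    lexicon: SemanticLexicon | None = None,
    policy: EdgeWeightPolicy = EdgeWeightPolicy(),
) -> list:
    """Blind, build the pair graph, and (for SC/ReSC) substitute classes."""
    if method.classes != "none" and lexicon is None:
        raise ValueError(f"method {method.name} needs a semantic lexicon")
    graphs = []
    for inst in instances:
        blinded = blind_entities(inst.sentence, inst.pair)
        graph = build_pair_graph(blinded, inst.pair, method.structure, policy)
        if method.classes != "none":
            tagging = annotate_tokens(blinded, lexicon, refined=method.classes == "ReSC")
            graph = apply_semantic_classes(graph, tagging)
        graphs.append(graph)
    return graphs


@dataclass
class MethodResult:
    method: str
    prf: evaluation.PRF
    threshold: float
    test_scores: np.ndarray
    test_pred: list
    auc: float | None
    per_doc_f1: dict
    roc: evaluation.RocCurve | None = None


@dataclass
class ExperimentResult:
    methods: dict  # name -> MethodResult
    significance: dict  # (method, baseline) -> (t, p, significant)

    def table(self):
        import pandas as pd

        rows = []
        for name, res in self.methods.items():
            sig_dep = self.significance.get((name, "DEP"))
            sig_pas = self.significance.get((name, "PAS"))
            rows.append(
                {
                    "method": name,
                    "P": res.prf.precision,
                    "R": res.prf.recall,
                    "F1": res.prf.f1,
                    "AUC": res.auc,
                    "threshold": res.threshold,
                    "sig_vs_DEP": sig_dep[2] if sig_dep else None,
                    "sig_vs_PAS": sig_pas[2] if sig_pas else None,
                }
            )
        return pd.DataFrame(rows).set_index("method")


def _labels_to_y(instances) -> np.ndarray:
    y = []
    for inst in instances:
        if inst.pair.gold_label is None:
            raise ValueError(
                f"instance {inst.pair} carries no gold label; cannot train/evaluate"
            )
        y.append(1.0 if inst.pair.gold_label == DDI else -1.0)
    return np.asarray(y)


def _per_doc_f1(instances, pred) -> dict:
    by_doc: dict[str, list] = {}
    for inst, p in zip(instances, pred):
        by_doc.setdefault(inst.doc_id, []).append((p, inst.pair.gold_label))
    return {
        doc: evaluation.precision_recall_f1([p for p, _ in rows], [g for _, g in rows]).f1
        for doc, rows in sorted(by_doc.items())
    }


def run_experiment(
    train_docs,
    test_docs,
    methods,
    lexicon: SemanticLexicon | None = None,
    config: ExperimentConfig = ExperimentConfig(),
) -> ExperimentResult:
    """Run the listed method variants end-to-end; deterministic given seeds.

    The label vocabulary, basis selection and decision threshold are derived
    from the training split only; labels seen only at test time contribute
    zero kernel mass.
    """
    methods = [m if isinstance(m, MethodSpec) else MethodSpec.parse(m) for m in methods]
    train_instances = collect_instances(train_docs)
    test_instances = collect_instances(test_docs)
    y_train = _labels_to_y(train_instances)
    gold_test = [inst.pair.gold_label for inst in test_instances]
    doc_ids = [inst.doc_id for inst in train_instances]

    results: dict[str, MethodResult] = {}
    for method in methods:
        logger.info("method %s: building %d+%d graphs", method.name,
                    len(train_instances), len(test_instances))
        train_graphs = build_graphs(train_instances, method, lexicon, config.policy)
        test_graphs = build_graphs(test_instances, method, lexicon, config.policy)
        vocab = build_label_vocabulary(train_graphs)
        F_tr = feature_matrix_rows(train_graphs, vocab)
        F_te = feature_matrix_rows(test_graphs, vocab, on_unknown="drop")
        K_tr = cross_gram_matrix(F_tr, F_tr)

        threshold, _ = rls.tune_threshold_lodo(
            K_tr, y_train, doc_ids,
            lam=config.lam, n_basis=config.n_basis, seed=config.seed,
        )
        basis = rls.select_basis(list(range(len(train_instances))),
                                 n_basis=config.n_basis, seed=config.seed)
        alpha = rls.fit_sparse_rls(
            K_tr[np.ix_(basis, range(len(train_instances)))],
            K_tr[np.ix_(basis, basis)],
            y_train, config.lam,
        )
        scores = rls.predict_scores(alpha, cross_gram_matrix(F_tr[basis], F_te))
        pred = rls.classify(scores, threshold)
        prf = evaluation.precision_recall_f1(pred, gold_test)
        auc = roc = None
        if len(set(gold_test)) > 1:
            roc = evaluation.roc_points(scores, gold_test)
            auc = roc.auc
        results[method.name] = MethodResult(
            method=method.name, prf=prf, threshold=threshold,
            test_scores=scores, test_pred=pred, auc=auc,
            per_doc_f1=_per_doc_f1(test_instances, pred), roc=roc,
        )

    significance = {}
    for baseline in ("DEP", "PAS"):
        if baseline not in results:
            continue
        base = results[baseline]
        for name, res in results.items():
            if name == baseline:
                continue
            docs = sorted(set(base.per_doc_f1) & set(res.per_doc_f1))
            if len(docs) >= 2:
                significance[(name, baseline)] = evaluation.paired_t_test(
                    [res.per_doc_f1[d] for d in docs],
                    [base.per_doc_f1[d] for d in docs],
                )
    return ExperimentResult(results, significance)


# ---------------------------------------------------------------------------
# Model persistence (train / predict verbs)
# ---------------------------------------------------------------------------

def _vocab_hash(vocab: LabelVocabulary) -> str:
    return hashlib.sha256("\x00".join(vocab.labels).encode()).hexdigest()[:16]


def train_model(
    train_docs,
    method: MethodSpec,
    lexicon: SemanticLexicon | None = None,
    config: ExperimentConfig = ExperimentConfig(),
) -> dict:
    """Train one variant and return a JSON-serializable model bundle."""
    instances = collect_instances(train_docs)
    y = _labels_to_y(instances)
    graphs = build_graphs(instances, method, lexicon, config.policy)
    vocab = build_label_vocabulary(graphs)
    F = feature_matrix_rows(graphs, vocab)
    K = cross_gram_matrix(F, F)
    threshold, _ = rls.tune_threshold_lodo(
        K, y, [i.doc_id for i in instances],
        lam=config.lam, n_basis=config.n_basis, seed=config.seed,
    )
    basis = rls.select_basis(list(range(len(instances))), config.n_basis, config.seed)
    alpha = rls.fit_sparse_rls(K[np.ix_(basis, range(len(instances)))],
                               K[np.ix_(basis, basis)], y, config.lam)
    model = rls.RLSModel(
        basis_ids=[f"{instances[b].doc_id}/{instances[b].pair.sentence_id}/"
                   f"{instances[b].pair.e1}-{instances[b].pair.e2}" for b in basis],
        alpha=alpha, lam=config.lam, threshold=threshold,
        vocabulary_hash=_vocab_hash(vocab),
    )
    # the basis graphs' flattened features are needed to score new instances
    return {
        "format_version": 1,
        "method": method.name,
        "model": json.loads(model.to_json()),
        "vocabulary": list(vocab.labels),
        "basis_rows": [
            {"indices": F[b].indices.tolist(), "data": F[b].data.tolist()}
            for b in basis
        ],
        "policy": {
            "on_path": config.policy.on_path,
            "off_path": config.policy.off_path,
            "linear": config.policy.linear,
        },
    }


def predict(bundle: dict, docs, lexicon: SemanticLexicon | None = None) -> list:
    """Score candidate pairs of ``docs`` with a trained model bundle.

    Returns one record per pair: doc/sentence/pair ids, raw score, label.
    """
    import scipy.sparse as sp

    method = MethodSpec.parse(bundle["method"])
    vocab = LabelVocabulary(bundle["vocabulary"])
    if _vocab_hash(vocab) != bundle["model"]["vocabulary_hash"]:
        raise ValueError("model vocabulary hash mismatch; refusing to score")
    model = rls.RLSModel.from_json(json.dumps(bundle["model"]))
    policy = EdgeWeightPolicy(**bundle["policy"])
    dim = len(vocab) ** 2
    F_basis = sp.vstack(
        [
            sp.csr_matrix(
                (row["data"], row["indices"], [0, len(row["indices"])]),
                shape=(1, dim),
            )
            for row in bundle["basis_rows"]
        ],
        format="csr",
    )
    instances = collect_instances(docs)
    if not instances:
        return []
    graphs = build_graphs(instances, method, lexicon, policy)
    F = feature_matrix_rows(graphs, vocab, on_unknown="drop")
    scores = rls.predict_scores(model.alpha, cross_gram_matrix(F_basis, F))
    labels = rls.classify(scores, model.threshold)
    return [
        {
            "doc_id": inst.doc_id,
            "sentence_id": inst.pair.sentence_id,
            "e1": inst.pair.e1,
            "e2": inst.pair.e2,
            "score": float(s),
            "label": lab,
        }
        for inst, s, lab in zip(instances, scores, labels)
    ]
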