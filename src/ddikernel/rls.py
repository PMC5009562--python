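"""Sparse regularized least squares (least-squares SVM) over precomputed
graph kernels.

The learner uses the subset-of-regressors approximation: a basis B of at
most ``n_basis`` training instances (uniformly sampled) parameterizes the
decision function

    score(x) = sum_{b in B} alpha_b K(x, x_b),

with alpha solving the regularized normal equations

    (K_BT K_BT^T + lambda K_BB) alpha = K_BT y,

where K_BT is the basis x training kernel block and y in {+1 (DDI),
-1 (NDDI)}.  With the full training set as basis this is exactly dense RLS,
alpha = (K + lambda I)^{-1} y.

The decision threshold on the raw score is picked by leave-one-document-out
cross-validation on the training set: each document's instances are scored
by a model fit on the remaining documents, the held-out scores are pooled,
and the threshold is the midpoint between consecutive sorted scores that
maximizes pooled F1 (ties resolved toward the lower threshold).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RLSModel",
    "select_basis",
    "fit_sparse_rls",
    "predict_scores",
    "best_f1_threshold",
    "tune_threshold_lodo",
    "classify",
]

DDI = "DDI"
NDDI = "NDDI"
JITTER = 1e-8
# Gram entries are O(1e2-1e3) without normalization, so the useful
# regularization scale is well above one
DEFAULT_LAMBDA = 100.0


@dataclass
class RLSModel:
    basis_ids: list
    alpha: np.ndarray
    lam: float
    threshold: float | None = None
    vocabulary_hash: str | None = None

    def __post_init__(self) -> None:
        if len(self.alpha) != len(self.basis_ids):
            raise ValueError("alpha length must equal the number of basis instances")

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": 1,
                "basis_ids": list(self.basis_ids),
                "alpha": [float(a) for a in self.alpha],
                "lambda": self.lam,
                "threshold": self.threshold,
                "vocabulary_hash": self.vocabulary_hash,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RLSModel":
        obj = json.loads(text)
        return cls(
            basis_ids=obj["basis_ids"],
            alpha=np.asarray(obj["alpha"], dtype=float),
            lam=obj["lambda"],
            threshold=obj["threshold"],
            vocabulary_hash=obj.get("vocabulary_hash"),
        )


def select_basis(ids, n_basis: int = 500, seed: int = 0) -> list:
    """Uniform sample of min(n_basis, |ids|) instance ids without replacement,
    returned in original corpus order (deterministic for a given seed)."""
    ids = list(ids)
    if n_basis < 1:
        raise ValueError("n_basis must be >= 1")
    if n_basis >= len(ids):
        return ids
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n_basis, replace=False)
    return [ids[i] for i in sorted(chosen)]


def fit_sparse_rls(K_BT: np.ndarray, K_BB: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Solve the subset-of-regressors normal equations for alpha.

    K_BT: (n_basis, n_train) kernel block basis x training;
    K_BB: (n_basis, n_basis) basis block (symmetric); y in {+1, -1}.
    A singular system is retried with a small ridge jitter (warned).
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    K_BT = np.atleast_2d(np.asarray(K_BT, dtype=float))
    K_BB = np.atleast_2d(np.asarray(K_BB, dtype=float))
    y = np.asarray(y, dtype=float)
    lhs = K_BT @ K_BT.T + lam * K_BB
    rhs = K_BT @ y
    # the system is symmetric PSD but often rank-deficient (duplicate
    # sentences yield identical kernel rows), so factor by Cholesky and fall
    # back to a ridge jitter scaled to the matrix's own magnitude
    from scipy import linalg as sla

    try:
        c, low = sla.cho_factor(lhs)
        alpha = sla.cho_solve((c, low), rhs)
        if not np.all(np.isfinite(alpha)):
            raise np.linalg.LinAlgError("non-finite solution")
    except (np.linalg.LinAlgError, sla.LinAlgError):
        warnings.warn(
            "singular RLS system; re-solving with ridge jitter", RuntimeWarning
        )
        scale = max(float(np.mean(np.diag(lhs))), 1.0)
        ridge = JITTER * scale * np.eye(lhs.shape[0])
        c, low = sla.cho_factor(lhs + ridge)
        alpha = sla.cho_solve((c, low), rhs)
    return alpha


def predict_scores(alpha: np.ndarray, k_cols: np.ndarray) -> np.ndarray:
    """scores = alpha^T K(basis, new); k_cols is (n_basis, n_new)."""
    k_cols = np.atleast_2d(np.asarray(k_cols, dtype=float))
    if k_cols.shape[0] != len(alpha):
        raise ValueError(
            f"kernel column block has {k_cols.shape[0]} rows for {len(alpha)} basis vectors"
        )
    return np.asarray(alpha) @ k_cols


def _f1_at(scores: np.ndarray, y: np.ndarray, threshold: float) -> float:
    pred = scores > threshold
    pos = y > 0
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def best_f1_threshold(scores, y) -> tuple[float, float]:
    """F1-optimal cut on pooled scores; returns (threshold, best F1).

    Candidates are midpoints between consecutive distinct sorted scores, plus
    one cut below the minimum (predict everything positive).  Ties go to the
    lower threshold.  If no cut yields F1 > 0 (e.g. no gold positives) the
    threshold is placed above the maximum score, predicting nothing positive.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot tune a threshold on zero scores")
    distinct = np.unique(scores)
    candidates = [distinct[0] - 1.0]
    candidates.extend((distinct[:-1] + distinct[1:]) / 2.0)
    best_thr, best_f1 = None, -1.0
    for thr in candidates:
        f1 = _f1_at(scores, y, thr)
        if f1 > best_f1:
            best_thr, best_f1 = thr, f1
    if best_f1 <= 0.0:
        return float(distinct[-1] + 1.0), 0.0
    return float(best_thr), float(best_f1)


def tune_threshold_lodo(
    K: np.ndarray,
    y: np.ndarray,
    doc_ids,
    lam: float = DEFAULT_LAMBDA,
    n_basis: int = 500,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Leave-one-document-out threshold selection.

    K is the full training Gram matrix, y the +-1 labels, doc_ids the
    document of each instance.  The basis is drawn once from all training
    instances; each fold restricts it to the remaining documents' instances.
    Returns (threshold, pooled held-out scores aligned with instances).
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    doc_ids = list(doc_ids)
    docs = sorted(set(doc_ids), key=str)
    if len(docs) < 2:
        raise ValueError("leave-one-document-out needs at least two documents")
    n = len(y)
    basis = select_basis(list(range(n)), n_basis=n_basis, seed=seed)
    pooled = np.full(n, np.nan)
    for doc in docs:
        held = [i for i in range(n) if doc_ids[i] == doc]
        rest = [i for i in range(n) if doc_ids[i] != doc]
        fold_basis = [b for b in basis if b in set(rest)] or rest
        K_BT = K[np.ix_(fold_basis, rest)]
        K_BB = K[np.ix_(fold_basis, fold_basis)]
        alpha = fit_sparse_rls(K_BT, K_BB, y[rest], lam)
        pooled[held] = predict_scores(alpha, K[np.ix_(fold_basis, held)])
    threshold, _ = best_f1_threshold(pooled, y)
    return threshold, pooled


def classify(scores, threshold: float) -> list:
    """DDI iff score > threshold."""
    return [DDI if s > threshold else NDDI for s in np.asarray(scores, dtype=float)]
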