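"""5-fold cross-validation over lncRNA-disease pairs and ranking metrics.

Positives and negatives are each partitioned into five random subsets; fold
f holds out positive subset f and negative subset f as its test set.  For
each fold the held-out positives are removed from the association matrix
everywhere it is consumed — similarity computation, graph construction and
the loss masks — so no information about test edges reaches training.  Test
scores are pooled over the five folds (each pair is scored exactly once)
and AUC, AUPR, F1, MCC and per-disease top-k recall are computed on the
pooled set.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    matthews_corrcoef,
    precision_recall_curve,
    roc_auc_score,
)

from .datasets import AssociationDataset, Config
from .networks import build_views
from .similarity import build_similarity_bundle
from .training import MaskPair, TrainResult, train_model

__all__ = [
    "CVResult",
    "five_fold_split",
    "compute_metrics",
    "topk_recall",
    "run_cross_validation",
]

N_FOLDS = 5


@dataclasses.dataclass
class CVResult:
    fold_of_pair: np.ndarray     # nl x nd int matrix, fold index of each pair
    scores: np.ndarray           # nl x nd pooled test scores
    labels: np.ndarray           # nl x nd ground-truth associations
    auc: float
    aupr: float
    f1: float
    mcc: float
    threshold: float
    topk_recall: dict            # k -> recall over pooled test positives
    loss_traces: list            # per-fold training loss traces
    view: str


def five_fold_split(dataset: AssociationDataset, seed: int) -> np.ndarray:
    """Assign every lncRNA-disease pair a fold in {0..4}.

    Positives and negatives are shuffled and split into near-equal fifths
    independently, so each fold's test set preserves the class ratio.
    """
    LD = dataset.LD
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(LD.ravel() == 1)
    neg = np.flatnonzero(LD.ravel() == 0)
    if len(pos) < N_FOLDS:
        raise ValueError(f"need at least {N_FOLDS} positives, got {len(pos)}")
    fold = np.empty(LD.size, dtype=int)
    for idx in (pos, neg):
        perm = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(perm, N_FOLDS)):
            fold[chunk] = f
    return fold.reshape(LD.shape)


def compute_metrics(scores, labels, threshold: float | None = None):
    """AUC, AUPR, and F1/MCC at a threshold.

    When ``threshold`` is None the F1-maximizing threshold on the given
    scores is used and reported.  Returns
    ``(auc, aupr, f1, mcc, threshold)``.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    if threshold is None:
        prec, rec, thr = precision_recall_curve(labels, scores)
        with np.errstate(invalid="ignore", divide="ignore"):
            f1s = 2 * prec[:-1] * rec[:-1] / (prec[:-1] + rec[:-1])
        f1s = np.nan_to_num(f1s)
        threshold = float(thr[int(np.argmax(f1s))])
    pred = (scores >= threshold).astype(int)
    f1 = float(f1_score(labels, pred, zero_division=0))
    mcc = float(matthews_corrcoef(labels, pred))
    return auc, aupr, f1, mcc, float(threshold)


def topk_recall(score_matrix: np.ndarray, positives: np.ndarray, k: int,
                candidates: np.ndarray | None = None) -> float:
    """Per-disease top-k recall.

    For each disease, its candidate lncRNAs (all by default) are ranked by
    score descending, ties broken by lncRNA index ascending; the top k are
    called positive.  Returns captured positives / total positives.
    """
    scores = np.asarray(score_matrix, dtype=float)
    positives = np.asarray(positives) != 0
    nl, nd = scores.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > nl:
        warnings.warn(f"k={k} exceeds lncRNA count {nl}; clamped",
                      stacklevel=2)
        k = nl
    if candidates is None:
        candidates = np.ones_like(positives, dtype=bool)
    captured = 0
    total = int(positives.sum())
    if total == 0:
        raise ValueError("no positives to recall")
    for j in range(nd):
        cand = np.flatnonzero(candidates[:, j])
        if cand.size == 0:
            continue
        # stable sort on negated scores -> ties resolve by ascending index
        order = cand[np.argsort(-scores[cand, j], kind="stable")]
        captured += int(positives[order[:k], j].sum())
    return captured / total


def run_cross_validation(dataset: AssociationDataset, config: Config,
                         semantic_DS: np.ndarray | None = None,
                         topk: tuple = (),
                         ) -> CVResult:
    """Train and score each fold, pool the test predictions, and evaluate.

    Similarities and both graph views are rebuilt per fold from the
    training-fold association matrix.  The per-fold model seed derives from
    ``config.seed`` and the fold index.
    """
    LD = dataset.LD
    fold = five_fold_split(dataset, config.seed)
    pooled = np.zeros_like(LD, dtype=float)
    traces = []
    for f in range(N_FOLDS):
        test = fold == f
        train_LD = LD * ~test  # test positives removed everywhere downstream
        bundle = build_similarity_bundle(dataset, config, semantic_DS,
                                         LD=train_LD)
        views = build_views(bundle, train_LD, dataset.LM, view=config.view)
        masks = MaskPair(omega_P=(LD == 1) & ~test,
                         omega_N=(LD == 0) & ~test)
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, f]))
        result: TrainResult = train_model(views, train_LD, masks, config,
                                          rng=rng)
        pooled[test] = result.scores[test]
        traces.append(result.loss_trace)
    auc, aupr, f1, mcc, thr = compute_metrics(
        pooled, LD, config.classification_threshold)
    recalls = {int(k): topk_recall(pooled, LD, int(k)) for k in topk}
    return CVResult(fold_of_pair=fold, scores=pooled, labels=LD.copy(),
                    auc=auc, aupr=aupr, f1=f1, mcc=mcc, threshold=thr,
                    topk_recall=recalls, loss_traces=traces, view=config.view)
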