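"""Retrieval and classification evaluation.

Retrieval quality is scored against class-label ground truth: for a query
of class l_0, database proteins of the same class are the *relevant* items.
Treating the top k of a ranking as hits yields per-cutoff confusion counts,
the ROC curve (FPR_k, TPR_k), the precision-recall curve and the area under
the ROC curve (AUC), here integrated trapezoidally over the step curve
anchored at (0, 0).  Classification quality uses the leave-one-out
protocol: each database protein in turn becomes an unlabeled query, its
class is predicted from its nearest neighbor under the evaluated measure,
and accuracy is the fraction predicted correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .context import rank_neighbors
from .measures import PairwiseMatrix
from .regularize import IterationConfig, prodis_iterate, rank_database

__all__ = [
    "RankingEvaluation",
    "confusion_at_k",
    "roc_and_auc",
    "precision_recall",
    "mean_auc_over_queries",
    "loo_classification_accuracy",
]


@dataclass
class RankingEvaluation:
    """Per-cutoff confusion counts and rates of one ranked retrieval list.

    Arrays are indexed by cutoff k = 1..N (position 0 holds k = 1).  At
    every k the counts conserve: TP + FN equals the number of relevant
    items and FP + TN the number of irrelevant ones.
    """

    k: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float

    def curve_rows(self) -> list[dict]:
        """Row dicts (k, tpr, fpr, precision, recall) for TSV export."""
        return [
            {
                "k": int(self.k[t]),
                "tpr": float(self.tpr[t]),
                "fpr": float(self.fpr[t]),
                "precision": float(self.precision[t]),
                "recall": float(self.recall[t]),
            }
            for t in range(len(self.k))
        ]


def _as_relevance(ranking: Sequence, relevant: Iterable) -> np.ndarray:
    rel = set(relevant)
    return np.array([item in rel for item in ranking], dtype=bool)


def confusion_at_k(
    ranking: Sequence, relevant: Iterable, k: int
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) when the top k of the ranking count as hits."""
    n = len(ranking)
    if not 1 <= k <= n:
        raise ValueError(f"cutoff k must be in [1, {n}], got {k}")
    hits = _as_relevance(ranking, relevant)
    n_rel = int(hits.sum())
    tp = int(hits[:k].sum())
    fp = k - tp
    fn = n_rel - tp
    tn = n - k - fn
    return tp, fp, tn, fn


def roc_and_auc(ranking: Sequence, relevant: Iterable) -> RankingEvaluation:
    """Full ROC / precision-recall sweep over cutoffs k = 1..N, with AUC.

    AUC is the trapezoidal area under the (FPR, TPR) polyline anchored at
    (0, 0); the k = N point is (1, 1) by construction.  On tie-free scores
    this equals the probability that a random relevant item is ranked ahead
    of a random irrelevant one (the Mann-Whitney statistic).
    """
    hits = _as_relevance(ranking, relevant)
    n = len(ranking)
    n_rel = int(hits.sum())
    n_irr = n - n_rel
    if n_rel == 0 or n_irr == 0:
        raise ValueError(
            "degenerate ground truth: need at least one relevant and one "
            f"irrelevant item (got {n_rel} relevant of {n})"
        )
    k = np.arange(1, n + 1)
    tp = np.cumsum(hits)
    fp = k - tp
    fn = n_rel - tp
    tn = n - k - fn
    tpr = tp / n_rel
    fpr = fp / n_irr
    precision = tp / k
    auc = float(
        np.trapezoid(np.concatenate(([0.0], tpr)), np.concatenate(([0.0], fpr)))
    )
    return RankingEvaluation(
        k=k,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        tpr=tpr,
        fpr=fpr,
        precision=precision,
        recall=tpr.copy(),
        auc=auc,
    )


def precision_recall(
    ranking: Sequence, relevant: Iterable
) -> tuple[np.ndarray, np.ndarray]:
    """(recall_k, precision_k) arrays for k = 1..N."""
    ev = roc_and_auc(ranking, relevant)
    return ev.recall, ev.precision


def mean_auc_over_queries(
    rankings: Sequence[Sequence], truths: Sequence[Iterable]
) -> float:
    """Arithmetic mean of per-query AUC over a set of queries."""
    if len(rankings) == 0:
        raise ValueError("need at least one query")
    if len(rankings) != len(truths):
        raise ValueError("rankings and truths must align")
    return float(np.mean([roc_and_auc(r, t).auc for r, t in zip(rankings, truths)]))


def _loo_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


def loo_classification_accuracy(
    matrix: PairwiseMatrix,
    labels: Sequence[str],
    config: Optional[IterationConfig] = None,
) -> float:
    """Leave-one-out nearest-neighbor classification accuracy.

    Every protein in turn is held out and assigned the class label of its
    nearest neighbor among the remaining proteins.  With ``config=None``
    the base matrix is used directly.  With a refinement config, the
    refinement is re-run per held-out protein with that protein moved to
    index 0 as an *unlabeled* query — its label is hidden from pair
    sampling and SVM training, so the protocol is leakage-free — and the
    prediction is the label of the top-ranked database protein under the
    refined matrix.
    """
    if matrix.has_query:
        raise ValueError("leave-one-out expects a fully labeled database matrix")
    n = matrix.n
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 proteins")
    if len(labels) != n or any(l is None for l in labels):
        raise ValueError("every database protein must carry a label")
    correct = 0
    for i in range(n):
        if config is None:
            nn = rank_neighbors(matrix, i)[0]
            predicted = labels[nn]
        else:
            qmat, order = matrix.with_query(i)
            qlabels: list[Optional[str]] = [None] + [labels[j] for j in order[1:]]
            cfg_i = replace(config, seed=_loo_seed(config.seed, i))
            refined = prodis_iterate(qmat, qlabels, cfg_i)
            predicted = qlabels[rank_database(refined)[0]]
        correct += predicted == labels[i]
    return correct / n
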