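"""Hierarchical neighbor contexts and contextual dissimilarities.

The *context* of a protein is its K nearest neighbors under the current
pairwise matrix.  Splitting the neighbor list by rank into P consecutive
blocks of size kappa gives the *hierarchical sub-contexts* N_p(i): block 1
holds the kappa nearest neighbors, block 2 the next kappa, and so on, so
the blocks partition the top ``K = P * kappa`` neighbors.

For a pair (i, j) the *sub-contextual dissimilarity* at level p,

    d_ij(p) = (1 / kappa^2) * sum_{m in N_p(i), n in N_p(j)} d_mn,

is the mean pairwise score between corresponding blocks, and the
*contextual dissimilarity* r_ij is the mean of the P levels.  The stacked
vector ``[d_ij(1), ..., d_ij(P)]`` is the feature the supervised
regularizer classifies.  In similarity mode the same averages are
contextual similarities; the construction is identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .measures import PairwiseMatrix

__all__ = [
    "HierarchicalContext",
    "rank_neighbors",
    "hierarchical_context",
    "context_vector",
    "all_context_vectors",
    "flat_contextual_dissimilarity",
    "mean_contextual_dissimilarity",
]


@dataclass(frozen=True)
class HierarchicalContext:
    """Per-protein neighbor blocks N_p(i).

    ``blocks[i, p]`` holds the kappa neighbor indices whose 1-based rank in
    protein i's neighbor list is ``p*kappa + 1 .. (p+1)*kappa`` (``p`` is
    0-based here).  Blocks of one protein are disjoint, never contain the
    protein itself, and concatenate to its K nearest neighbors in rank
    order.
    """

    blocks: np.ndarray  # (n, P, kappa) integer indices
    kappa: int
    levels: int

    @property
    def K(self) -> int:
        """Total context size P * kappa."""
        return self.kappa * self.levels

    def blocks_of(self, i: int) -> np.ndarray:
        """The (P, kappa) block array of protein ``i``."""
        return self.blocks[i]

    def to_dict(self, ids: Sequence[str]) -> dict:
        """JSON-friendly dump: protein id -> list of P id-lists."""
        return {
            ids[i]: [[ids[m] for m in self.blocks[i, p]] for p in range(self.levels)]
            for i in range(self.blocks.shape[0])
        }


def rank_neighbors(
    matrix: PairwiseMatrix, i: int, exclude: Sequence[int] = ()
) -> np.ndarray:
    """All other indices sorted from nearest to farthest from protein ``i``.

    Nearest means smallest entry in dissimilarity mode and largest entry in
    similarity mode.  Ties are broken by ascending index so rankings are
    deterministic.  ``exclude`` removes further indices from the candidate
    list (used to keep the query out of database contexts).
    """
    if not 0 <= i < matrix.n:
        raise IndexError(f"protein index {i} out of range for n={matrix.n}")
    drop = set(exclude) | {i}
    cand = np.array([j for j in range(matrix.n) if j not in drop], dtype=int)
    if cand.size == 0:
        return cand
    vals = matrix.M[i, cand]
    key = vals if matrix.mode == "dissimilarity" else -vals
    return cand[np.lexsort((cand, key))]


def hierarchical_context(
    matrix: PairwiseMatrix,
    kappa: int,
    levels: int,
    include_query: bool = False,
) -> HierarchicalContext:
    """Build the P blocks of kappa consecutive-rank neighbors per protein.

    When the matrix carries a query (index 0) the query is, by default,
    excluded from every candidate neighbor list: contexts are then built
    from database proteins only, and the query's own context also consists
    of database proteins.  Set ``include_query=True`` to let the query
    participate in database contexts.
    """
    if kappa < 1 or levels < 1:
        raise ValueError("kappa and levels must both be >= 1")
    n = matrix.n
    need = kappa * levels
    exclude_query = matrix.has_query and not include_query
    blocks = np.empty((n, levels, kappa), dtype=int)
    for i in range(n):
        exclude = (0,) if exclude_query and i != 0 else ()
        ranked = rank_neighbors(matrix, i, exclude=exclude)
        if ranked.size < need:
            raise ValueError(
                f"hierarchical context needs P*kappa = {need} neighbors but "
                f"protein {i} has only {ranked.size} available"
            )
        blocks[i] = ranked[:need].reshape(levels, kappa)
    return HierarchicalContext(blocks=blocks, kappa=kappa, levels=levels)


def context_vector(
    matrix: PairwiseMatrix, ctx: HierarchicalContext, i: int, j: int
) -> np.ndarray:
    """The P-vector of block-to-block mean scores for the pair (i, j).

    Entry p is the mean of ``M[m, n]`` over all ``m`` in N_p(i) and ``n``
    in N_p(j).  Symmetric in (i, j) because M is.
    """
    P = ctx.levels
    out = np.empty(P)
    for p in range(P):
        out[p] = matrix.M[np.ix_(ctx.blocks[i, p], ctx.blocks[j, p])].mean()
    return out


def all_context_vectors(
    matrix: PairwiseMatrix, ctx: HierarchicalContext
) -> np.ndarray:
    """Context vectors of every pair at once, shape ``(n, n, P)``.

    Level p of the result is ``A_p M A_p^T`` where ``A_p`` is the
    row-stochastic block-membership matrix (``1/kappa`` on the members of
    N_p(i)).  Because M is symmetric each level is symmetric, so the values
    computed for (i, j) serve (j, i) directly; the product is additionally
    re-symmetrized to make the reuse exact under floating point.
    """
    n = matrix.n
    P, k = ctx.levels, ctx.kappa
    out = np.empty((n, n, P))
    rows = np.repeat(np.arange(n), k)
    for p in range(P):
        A = np.zeros((n, n))
        A[rows, ctx.blocks[:, p, :].ravel()] = 1.0 / k
        S = A @ matrix.M @ A.T
        out[:, :, p] = (S + S.T) / 2.0
    return out


def flat_contextual_dissimilarity(
    matrix: PairwiseMatrix, ctx: HierarchicalContext, i: int, j: int
) -> float:
    """Scalar contextual dissimilarity r_ij: mean of the context vector.

    With ``levels=1`` this is exactly the single-context form — the mean
    pairwise score between the K nearest neighbors of i and of j.  With
    more levels it is the average of the per-block means, which weights
    near and far neighbor rings equally instead of pooling all K^2 pairs.
    """
    return float(context_vector(matrix, ctx, i, j).mean())


def mean_contextual_dissimilarity(r_values) -> float:
    """Average r̄ of contextual dissimilarities over all ordered pairs.

    The caller supplies r_ij for every ordered database pair, including the
    diagonal pairs (i, i) — a protein's context compared with itself is
    generally non-zero — matching the 1/N^2 normalization used by the
    unsupervised regularizer.
    """
    arr = np.asarray(r_values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot average an empty set of contextual dissimilarities")
    return float(arr.mean())
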