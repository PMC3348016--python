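"""Contextual regularization of pairwise protein measures.

Two regularizers share one iterative skeleton:

* **Unsupervised (hierarchical-context, "ContHC")** — each pairwise score is
  multiplied by the ratio of the pair's contextual dissimilarity to the
  database average, ``delta_ij = r_ij / r_bar``.  Pairs whose neighbor
  contexts are farther apart than average are pushed apart, and vice versa.

* **Supervised ("ContSHC")** — database class labels mark each labeled pair
  as *relevant* (same class, y = +1) or *irrelevant* (different class,
  y = -1).  A linear soft-margin SVM is trained to separate the P-level
  context vectors of the two pair classes; its signed decision value
  ``y~_ij = w . d_ij + b`` scores how relevant-looking a pair's context is,
  and the factor is ``delta_ij = exp(-y~_ij / sigma)`` in dissimilarity
  mode (``exp(+y~_ij / sigma)`` in similarity mode, where relevant-looking
  pairs should be boosted, not shrunk).

The iteration alternates coherently: contexts are rebuilt from the refined
matrix, factors are re-learned from the new contexts, and every entry is
updated multiplicatively, for T rounds (a fixed-point recursion).  Matrix
symmetry lets each unordered pair be computed once and mirrored.  Two
further efficiency levers are provided: :func:`restrict_to_top` runs the
refinement on the query's top-N' neighborhood only, and the pair sampler
draws a small balanced subset of relevant / irrelevant pairs for the SVM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import SVC

from .context import (
    HierarchicalContext,
    all_context_vectors,
    context_vector,
    hierarchical_context,
    rank_neighbors,
)
from .measures import Mode, PairwiseMatrix

__all__ = [
    "PairTrainingSet",
    "PairModel",
    "IterationConfig",
    "IterationDiagnostics",
    "unsupervised_factor",
    "enumerate_pairs",
    "build_pair_training_set",
    "train_pair_svm",
    "supervised_factor",
    "prodis_iterate",
    "restrict_to_top",
    "rank_database",
]

logger = logging.getLogger(__name__)

#: multiplicative factors are clamped to [exp(-30), exp(30)] so repeated
#: updates can never produce zeros, infinities or sign flips
FACTOR_LOG_BOUND = 30.0


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class PairTrainingSet:
    """Labeled context vectors of sampled protein pairs.

    ``y[g] = +1`` iff the two proteins of pair ``g`` share a class label
    (a relevant pair), else -1.  Pairs are unordered (i < j), never include
    a protein twice, and never involve an unlabeled protein.
    """

    pairs: list[tuple[int, int]]
    vectors: np.ndarray  # (n_pairs, P)
    y: np.ndarray  # (n_pairs,) in {+1, -1}
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.vectors.shape[0] != self.y.shape[0] or len(self.pairs) != self.y.shape[0]:
            raise ValueError("pairs, vectors and labels must have equal length")
        if not np.isin(self.y, (-1, 1)).all():
            raise ValueError("pair labels must be +1 or -1")

    @property
    def n_relevant(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_irrelevant(self) -> int:
        return int(np.sum(self.y == -1))


@dataclass
class PairModel:
    """Linear decision function f(d) = d . w + b over context vectors."""

    w: np.ndarray
    b: float
    margin_violations: int = 0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()

    def decision(self, d) -> np.ndarray | float:
        """Signed distance-like score of context vector(s) d."""
        d = np.asarray(d, dtype=float)
        return d @ self.w + self.b


@dataclass
class IterationConfig:
    """Parameters of one refinement run.

    Parameters
    ----------
    kappa:
        Sub-context (block) size.
    levels:
        Number P of hierarchical sub-contexts; total context K = P * kappa.
    iterations:
        Number T of coherent update rounds.
    sigma:
        Temperature of the supervised factor ``exp(-y~/sigma)``.  ``None``
        (default) adapts per iteration to the standard deviation of the
        decision values, keeping exponents O(1) on any data scale.
    supervised:
        Learn the factor from the pair SVM (True) or from the ratio to the
        average contextual dissimilarity (False).
    pairs_per_class:
        Balanced sampling budget: at most this many relevant and this many
        irrelevant pairs train the SVM each iteration.
    seed:
        Governs all pair sampling through deterministic per-iteration
        substreams.
    top_n:
        If set, refine only the query plus its top_n nearest database
        proteins (see :func:`restrict_to_top`); callers apply it before
        iterating.
    renormalize:
        Rescale the off-diagonal mean back to its initial value after each
        iteration, preventing multiplicative scale drift.  ``None`` resolves
        to True when iterations > 3.
    svm_c:
        Soft-margin C of the pair SVM.
    include_query_in_context:
        Let the (unlabeled) query appear in database proteins' neighbor
        contexts.  Off by default so contexts are query-independent.
    """

    kappa: int = 5
    levels: int = 3
    iterations: int = 3
    sigma: Optional[float] = None
    supervised: bool = True
    pairs_per_class: int = 100
    seed: int = 0
    top_n: Optional[int] = None
    renormalize: Optional[bool] = None
    svm_c: float = 1.0
    include_query_in_context: bool = False

    def __post_init__(self) -> None:
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.pairs_per_class < 1:
            raise ValueError("pairs_per_class must be >= 1")
        if self.top_n is not None and self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")

    def resolved_renormalize(self) -> bool:
        if self.renormalize is None:
            return self.iterations > 3
        return self.renormalize


@dataclass
class IterationDiagnostics:
    """One-line summary of a single refinement round."""

    iteration: int
    mean_factor: float
    sigma: Optional[float] = None
    training_size: Optional[int] = None
    margin_violations: Optional[int] = None


# ---------------------------------------------------------------------------
# factors
# ---------------------------------------------------------------------------


def unsupervised_factor(r_ij: float, r_bar: float) -> float:
    """Ratio-to-average regularization factor ``delta_ij = r_ij / r_bar``.

    In dissimilarity mode a pair whose contexts are farther apart than the
    database average (ratio > 1) has its dissimilarity inflated; in
    similarity mode the same ratio of contextual *similarities* boosts
    pairs with more-similar-than-average contexts.  The ratio is clamped to
    ``[exp(-30), exp(30)]`` so factors stay strictly positive.
    """
    if r_bar <= 0:
        raise ValueError(
            f"average contextual dissimilarity must be positive, got {r_bar}"
        )
    lo = float(np.exp(-FACTOR_LOG_BOUND))
    hi = float(np.exp(FACTOR_LOG_BOUND))
    return float(np.clip(r_ij / r_bar, lo, hi))


def supervised_factor(
    d_vec, model: PairModel, sigma: float, mode: Mode = "dissimilarity"
) -> float:
    """SVM-derived factor ``exp(-y~/sigma)`` (dissimilarity) or ``exp(+y~/sigma)``.

    ``y~ = f(d_vec)`` is the pair classifier's decision value: positive for
    relevant-looking contexts.  In dissimilarity mode such pairs are pulled
    together (factor < 1); in similarity mode they are pushed up
    (factor > 1).  A boundary pair (``y~ = 0``) is left unchanged.  The
    exponent is clamped to +/-30.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ytilde = float(model.decision(np.asarray(d_vec, dtype=float)))
    sign = 1.0 if mode == "similarity" else -1.0
    return float(np.exp(np.clip(sign * ytilde / sigma, -FACTOR_LOG_BOUND, FACTOR_LOG_BOUND)))


# ---------------------------------------------------------------------------
# pair sampling and the pair SVM
# ---------------------------------------------------------------------------


def enumerate_pairs(
    labels: Sequence[Optional[str]], indices: Sequence[int]
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """All unordered labeled pairs split into (relevant, irrelevant).

    Unlabeled entries (``None`` — the query) are skipped entirely.
    """
    lab = [i for i in indices if labels[i] is not None]
    relevant, irrelevant = [], []
    for a in range(len(lab)):
        for b in range(a + 1, len(lab)):
            i, j = lab[a], lab[b]
            (relevant if labels[i] == labels[j] else irrelevant).append((i, j))
    return relevant, irrelevant


def build_pair_training_set(
    matrix: PairwiseMatrix,
    ctx: HierarchicalContext,
    labels: Sequence[Optional[str]],
    budget: int,
    seed=None,
    _vectors: Optional[np.ndarray] = None,
) -> PairTrainingSet:
    """Sample a balanced set of relevant / irrelevant pairs with vectors.

    Up to ``budget`` pairs of each class are drawn without replacement from
    the labeled database pairs using the seeded generator; the selected
    pairs are then ordered canonically by (i, j) so the training set — and
    hence the fitted SVM — depends only on the sampled *set*, not on the
    draw order.  With a budget at least as large as both pair populations
    the sample is exactly the exhaustive enumeration.

    Each item carries the pair's context vector under the current matrix
    state (precomputed vectors may be passed internally to avoid rework).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    relevant, irrelevant = enumerate_pairs(labels, matrix.database_indices)
    if not relevant:
        raise ValueError("no relevant (same-class) pairs available for training")
    if not irrelevant:
        raise ValueError("no irrelevant (different-class) pairs available for training")
    rng = np.random.default_rng(seed)
    chosen: list[tuple[int, int]] = []
    ys: list[int] = []
    for pool, y in ((relevant, 1), (irrelevant, -1)):
        k = min(budget, len(pool))
        idx = rng.choice(len(pool), size=k, replace=False)
        sel = sorted(pool[t] for t in idx)
        chosen.extend(sel)
        ys.extend([y] * k)
    if _vectors is not None:
        vecs = np.array([_vectors[i, j] for (i, j) in chosen])
    else:
        vecs = np.array([context_vector(matrix, ctx, i, j) for (i, j) in chosen])
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return PairTrainingSet(pairs=chosen, vectors=vecs, y=np.array(ys), seed=seed_int)


def train_pair_svm(
    training: PairTrainingSet, c_soft: float = 1.0, tol: float = 1e-4
) -> PairModel:
    """Fit the linear soft-margin SVM separating relevant from irrelevant pairs.

    Returns the hyperplane (w, b) of the decision function
    ``f(d) = d . w + b`` together with the number of training items that
    violate the unit margin ``y (d . w + b) >= 1`` — zero on a separable
    set solved to optimality with a large C.

    The solver operates on standardized vectors (context-dissimilarity
    levels can sit far from the origin on arbitrary scales, which stalls
    margin solvers); the fitted hyperplane is mapped back so the returned
    (w, b) act on raw context vectors.
    """
    if training.n_relevant == 0 or training.n_irrelevant == 0:
        raise ValueError("training set must contain both pair classes")
    mu = training.vectors.mean(axis=0)
    sd = training.vectors.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    svc = SVC(kernel="linear", C=c_soft, tol=tol)
    svc.fit((training.vectors - mu) / sd, training.y)
    w = np.asarray(svc.coef_).ravel() / sd
    b = float(svc.intercept_[0]) - float(w @ mu)
    margins = training.y * (training.vectors @ w + b)
    violations = int(np.sum(margins < 1.0 - 1e-6))
    return PairModel(w=w, b=b, margin_violations=violations)


# ---------------------------------------------------------------------------
# the coherent iteration
# ---------------------------------------------------------------------------


def _iteration_seeds(seed: int, iterations: int) -> list[int]:
    """Deterministic per-iteration sampling seeds derived from one run seed."""
    children = np.random.SeedSequence(seed).spawn(iterations)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def prodis_iterate(
    matrix: PairwiseMatrix,
    labels: Optional[Sequence[Optional[str]]] = None,
    config: Optional[IterationConfig] = None,
    history: Optional[list] = None,
) -> PairwiseMatrix:
    """Refine a pairwise matrix by T rounds of contextual regularization.

    Each round (a) rebuilds the hierarchical contexts from the current
    matrix, (b) computes the context vector of every pair, (c) derives a
    strictly positive factor per pair — supervised (a freshly trained pair
    SVM) or unsupervised (ratio to the database-average contextual
    dissimilarity) — and (d) multiplies every off-diagonal entry by its
    factor.  Factors are computed once per unordered pair via the symmetric
    level matrices, so the update preserves symmetry exactly; the diagonal
    is left untouched (zero in dissimilarity mode).

    ``labels`` must align with matrix indices, with ``None`` for the
    unlabeled query at index 0; it may be omitted entirely in unsupervised
    mode.  Pass a list as ``history`` to collect per-iteration
    :class:`IterationDiagnostics`.

    Returns the refined matrix; the input is not modified.
    """
    cfg = config or IterationConfig()
    n = matrix.n
    if labels is None:
        if cfg.supervised:
            raise ValueError("supervised refinement requires class labels")
        labels = [None] * n
    if len(labels) != n:
        raise ValueError(f"labels length {len(labels)} does not match matrix size {n}")
    if matrix.has_query and labels[0] is not None:
        raise ValueError("the query (index 0) must be unlabeled")

    mode = matrix.mode
    D = matrix.M.copy()
    off = ~np.eye(n, dtype=bool)
    init_off_mean = float(D[off].mean()) if n > 1 else 0.0
    renorm = cfg.resolved_renormalize() and init_off_mean > 0
    seeds = _iteration_seeds(cfg.seed, cfg.iterations)
    lo, hi = -FACTOR_LOG_BOUND, FACTOR_LOG_BOUND

    for t in range(cfg.iterations):
        current = PairwiseMatrix(D, mode, list(matrix.ids), matrix.has_query)
        ctx = hierarchical_context(
            current, cfg.kappa, cfg.levels, include_query=cfg.include_query_in_context
        )
        S = all_context_vectors(current, ctx)  # (n, n, P)
        training_size = violations = None
        sigma_used: Optional[float] = None
        if cfg.supervised:
            training = build_pair_training_set(
                current, ctx, labels, cfg.pairs_per_class, seeds[t], _vectors=S
            )
            model = train_pair_svm(training, cfg.svm_c)
            ytilde = (S.reshape(n * n, -1) @ model.w + model.b).reshape(n, n)
            if cfg.sigma is not None:
                sigma_used = cfg.sigma
            else:
                spread = float(np.std(ytilde[off])) if n > 1 else 0.0
                sigma_used = spread if spread > 1e-12 else 1.0
            sign = 1.0 if mode == "similarity" else -1.0
            delta = np.exp(np.clip(sign * ytilde / sigma_used, lo, hi))
            training_size = len(training.pairs)
            violations = model.margin_violations
        else:
            r = S.mean(axis=2)
            db = current.database_indices
            r_bar = float(r[np.ix_(db, db)].mean())
            if r_bar <= 0:
                raise ValueError(
                    "average contextual dissimilarity is not positive; "
                    "the matrix context is degenerate"
                )
            delta = np.clip(r / r_bar, np.exp(lo), np.exp(hi))

        D[off] *= delta[off]
        if renorm:
            cur = float(D[off].mean())
            if cur > 0:
                D[off] *= init_off_mean / cur
        D = (D + D.T) / 2.0

        diag = IterationDiagnostics(
            iteration=t + 1,
            mean_factor=float(delta[off].mean()),
            sigma=sigma_used,
            training_size=training_size,
            margin_violations=violations,
        )
        if history is not None:
            history.append(diag)
        logger.info(
            "iteration %d/%d: mean factor %.4f%s",
            t + 1,
            cfg.iterations,
            diag.mean_factor,
            "" if training_size is None else f", SVM pairs {training_size} ({violations} margin violations)",
        )

    return PairwiseMatrix(D, mode, list(matrix.ids), matrix.has_query)


# ---------------------------------------------------------------------------
# efficiency: top-N' restriction, and the final ranking
# ---------------------------------------------------------------------------


def restrict_to_top(
    matrix: PairwiseMatrix, n_prime: int
) -> tuple[PairwiseMatrix, np.ndarray]:
    """Sub-matrix over the query plus its n_prime nearest database proteins.

    Refining only the query's neighborhood assumes all relevant proteins
    appear among its top N' initial matches, cutting the per-query cost
    from O(N^2) to O(N'^2).  The retained database rows keep their original
    relative order (so tie-breaking is unchanged and ``n_prime = N``
    reproduces the input exactly).  Returns the sub-matrix and the map from
    new indices to original ones.
    """
    if not matrix.has_query:
        raise ValueError("restrict_to_top requires a matrix with the query at index 0")
    n_db = matrix.n - 1
    if not 1 <= n_prime <= n_db:
        raise ValueError(f"n_prime must be in [1, {n_db}], got {n_prime}")
    nearest = rank_neighbors(matrix, 0)[:n_prime]
    keep = np.concatenate(([0], np.sort(nearest)))
    sub = matrix.M[np.ix_(keep, keep)]
    ids = [matrix.ids[k] for k in keep]
    return PairwiseMatrix(sub, matrix.mode, ids, has_query=True), keep


def rank_database(matrix: PairwiseMatrix) -> np.ndarray:
    """Database indices ranked best-match-first against the query row.

    Ascending refined dissimilarity (descending similarity in similarity
    mode); ties broken by ascending index.
    """
    if not matrix.has_query:
        raise ValueError("rank_database requires a matrix with the query at index 0")
    return rank_neighbors(matrix, 0)
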