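"""Base pairwise similarity / dissimilarity measures on protein feature vectors.

Protein retrieval systems represent each protein (a structure domain, a
sequence, or any entity with a numeric descriptor) as a feature vector
``x_i`` and compare proteins through a pairwise score.  This module provides
the four standard base measures used throughout the package — cosine
similarity, the Jaccard index, the Tanimoto coefficient and the squared
Euclidean distance — together with the two in-memory containers everything
else operates on:

:class:`FeatureTable`
    rows of feature vectors with optional per-protein class labels, and
:class:`PairwiseMatrix`
    a symmetric matrix of pairwise scores tagged with its *mode*
    (``"similarity"`` or ``"dissimilarity"``).

By convention, when a query protein is present it occupies matrix index 0
and carries no class label; database proteins occupy indices ``1..N``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "Mode",
    "ZeroVectorError",
    "DegeneratePairError",
    "FeatureTable",
    "PairwiseMatrix",
    "cosine_similarity",
    "jaccard_index",
    "tanimoto_coefficient",
    "squared_euclidean",
    "measure_mode",
    "build_matrix",
    "MEASURES",
]

Mode = Literal["similarity", "dissimilarity"]

_SYMMETRY_ATOL = 1e-9


class ZeroVectorError(ValueError):
    """A measure was asked to score an all-zero vector in strict mode."""


class DegeneratePairError(ValueError):
    """A pair of vectors on which the measure is mathematically undefined."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """N proteins as d-dimensional feature vectors, optionally labeled.

    Parameters
    ----------
    ids:
        Unique protein identifiers, one per row.
    X:
        ``(N, d)`` array of real-valued features; row ``i`` is ``x_i``.
    labels:
        Optional per-row class label (e.g. a fold identifier).  ``None`` for
        an individual entry marks an unlabeled protein (the query);
        ``labels=None`` means no label column at all.
    """

    ids: list[str]
    X: np.ndarray
    labels: Optional[list[Optional[str]]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] < 1:
            raise ValueError(
                f"feature matrix must be 2-D with at least one column, got shape {self.X.shape}"
            )
        self.ids = [str(i) for i in self.ids]
        if len(self.ids) != self.X.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but {self.X.shape[0]} feature rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("protein ids must be unique")
        if self.labels is not None:
            if len(self.labels) != self.X.shape[0]:
                raise ValueError("labels length does not match number of rows")
            self.labels = [None if l is None else str(l) for l in self.labels]
            if any(l == "" for l in self.labels):
                raise ValueError("labeled rows must carry a non-empty label")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def label_of(self, index: int) -> Optional[str]:
        if self.labels is None:
            return None
        return self.labels[index]

    def subset(self, indices: Sequence[int]) -> "FeatureTable":
        """Return a new table containing the given rows, in the given order."""
        idx = list(indices)
        return FeatureTable(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx].copy(),
            labels=None if self.labels is None else [self.labels[i] for i in idx],
        )


@dataclass
class PairwiseMatrix:
    """Symmetric matrix of pairwise protein scores.

    ``mode`` records whether entries are similarities (larger = closer) or
    dissimilarities (smaller = closer); every ranking and context operation
    in the package consults it.  In dissimilarity mode all entries are
    non-negative with a zero diagonal.  In similarity mode the builders set
    the diagonal to each protein's self-score, which is the row maximum for
    the bounded measures (cosine / Jaccard / Tanimoto on non-zero rows).

    When ``has_query`` is true, index 0 is a query protein: it is unlabeled,
    never used for training, and by default excluded from the neighbor
    contexts of database proteins.
    """

    M: np.ndarray
    mode: Mode
    ids: list[str]
    has_query: bool = False

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] != self.M.shape[1]:
            raise ValueError(f"matrix must be square, got shape {self.M.shape}")
        self.ids = [str(i) for i in self.ids]
        if len(self.ids) != self.M.shape[0]:
            raise ValueError("ids length does not match matrix size")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("matrix ids must be unique")
        if self.mode not in ("similarity", "dissimilarity"):
            raise ValueError(
                f"mode must be 'similarity' or 'dissimilarity', got {self.mode!r}"
            )
        if not np.allclose(self.M, self.M.T, atol=_SYMMETRY_ATOL, rtol=1e-9):
            raise ValueError("matrix is not symmetric")
        # enforce exact symmetry so downstream reuse of (i, j) results for
        # (j, i) is exact rather than within round-off
        self.M = (self.M + self.M.T) / 2.0
        if self.mode == "dissimilarity":
            if (self.M < -_SYMMETRY_ATOL).any():
                raise ValueError("dissimilarity entries must be non-negative")
            if np.abs(np.diag(self.M)).max(initial=0.0) > _SYMMETRY_ATOL:
                raise ValueError("dissimilarity diagonal must be zero")
            np.clip(self.M, 0.0, None, out=self.M)
            np.fill_diagonal(self.M, 0.0)

    @property
    def n(self) -> int:
        """Total number of rows (database proteins plus query, if any)."""
        return self.M.shape[0]

    @property
    def database_indices(self) -> np.ndarray:
        """Indices of database proteins (everything except a query row)."""
        return np.arange(1, self.n) if self.has_query else np.arange(self.n)

    def copy(self) -> "PairwiseMatrix":
        return PairwiseMatrix(self.M.copy(), self.mode, list(self.ids), self.has_query)

    def with_query(self, index: int) -> tuple["PairwiseMatrix", np.ndarray]:
        """Move row ``index`` to position 0 and mark it as the query.

        Returns the permuted matrix and the index map ``order`` such that
        new row ``k`` is old row ``order[k]``.  The relative order of the
        remaining rows is preserved, which keeps index-based tie-breaking
        stable.
        """
        if not 0 <= index < self.n:
            raise IndexError(f"row index {index} out of range for n={self.n}")
        order = np.array([index] + [j for j in range(self.n) if j != index])
        sub = self.M[np.ix_(order, order)]
        return (
            PairwiseMatrix(sub, self.mode, [self.ids[j] for j in order], has_query=True),
            order,
        )


# ---------------------------------------------------------------------------
# the four base measures
# ---------------------------------------------------------------------------


def _as_pair(x_i, x_j) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(x_i, dtype=float)
    b = np.asarray(x_j, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("feature vectors must be 1-D")
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"dimension mismatch: {a.shape[0]} vs {b.shape[0]}"
        )
    return a, b


def cosine_similarity(x_i, x_j, zero_policy: str = "zero") -> float:
    """Cosine of the angle between two feature vectors.

    Returns ``x_i . x_j / (||x_i|| ||x_j||)``, in ``[-1, 1]``.  The value is
    undefined when either vector has zero norm; under the default
    ``zero_policy="zero"`` such pairs score 0 (maximally dissimilar) with a
    warning, while ``zero_policy="raise"`` raises :class:`ZeroVectorError`.
    """
    a, b = _as_pair(x_i, x_j)
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        if zero_policy == "raise":
            raise ZeroVectorError("cosine similarity undefined for a zero vector")
        if zero_policy != "zero":
            raise ValueError(f"unknown zero_policy {zero_policy!r}")
        warnings.warn(
            "cosine similarity of a zero vector treated as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def jaccard_index(x_i, x_j, threshold: float = 0.0) -> float:
    """Jaccard index of the supports of two feature vectors.

    The set measure |A ∩ B| / |A ∪ B| applied to numeric vectors by reading
    every coordinate with value strictly greater than ``threshold`` as a set
    member.  Two empty supports are treated as identical sets (returns 1).
    """
    a, b = _as_pair(x_i, x_j)
    sa = a > threshold
    sb = b > threshold
    union = int(np.sum(sa | sb))
    if union == 0:
        return 1.0
    return float(np.sum(sa & sb) / union)


def tanimoto_coefficient(x_i, x_j) -> float:
    """Tanimoto coefficient, the real-valued generalization of Jaccard.

    Returns ``x_i . x_j / (||x_i||^2 + ||x_j||^2 - x_i . x_j)``.  On binary
    0/1 vectors this coincides with :func:`jaccard_index`.  The denominator
    vanishes only when both vectors are zero, which raises
    :class:`DegeneratePairError`.
    """
    a, b = _as_pair(x_i, x_j)
    dot = float(np.dot(a, b))
    denom = float(np.dot(a, a) + np.dot(b, b) - dot)
    if denom == 0.0:
        raise DegeneratePairError(
            "Tanimoto coefficient undefined: zero denominator for the pair "
            f"{a.tolist()} / {b.tolist()}"
        )
    return dot / denom


def squared_euclidean(x_i, x_j) -> float:
    """Squared Euclidean distance, the package's base dissimilarity."""
    a, b = _as_pair(x_i, x_j)
    diff = a - b
    return float(np.dot(diff, diff))


#: measure name -> (pairwise function, natural mode)
MEASURES: dict[str, tuple] = {
    "cosine": (cosine_similarity, "similarity"),
    "jaccard": (jaccard_index, "similarity"),
    "tanimoto": (tanimoto_coefficient, "similarity"),
    "sqeuclidean": (squared_euclidean, "dissimilarity"),
}

_ALIASES = {"squared_euclidean": "sqeuclidean", "euclidean2": "sqeuclidean"}


def _resolve_measure(name: str):
    key = _ALIASES.get(name, name)
    if key not in MEASURES:
        valid = sorted(set(MEASURES) | set(_ALIASES))
        raise ValueError(f"unknown measure {name!r}; valid names: {', '.join(valid)}")
    return key, *MEASURES[key]


def measure_mode(name: str) -> Mode:
    """Natural mode (similarity / dissimilarity) of a named measure."""
    return _resolve_measure(name)[2]


def build_matrix(
    table: FeatureTable,
    measure: str,
    query_index: Optional[int] = None,
    **measure_kwargs,
) -> PairwiseMatrix:
    """Assemble the full pairwise matrix of a feature table under one measure.

    Every unordered pair is scored once with the named measure and mirrored,
    so the result is exactly symmetric.  If ``query_index`` is given that row
    is moved to matrix index 0 and the result is flagged ``has_query``.

    Parameters
    ----------
    table:
        Input feature vectors.
    measure:
        One of ``cosine``, ``jaccard``, ``tanimoto``, ``sqeuclidean``.
    query_index:
        Optional row to treat as the (unlabeled) query.
    measure_kwargs:
        Passed through to the pairwise function (e.g. ``zero_policy``,
        ``threshold``).
    """
    key, func, mode = _resolve_measure(measure)
    if query_index is not None:
        if not 0 <= query_index < table.n:
            raise IndexError(f"query_index {query_index} out of range")
        order = [query_index] + [j for j in range(table.n) if j != query_index]
        table = table.subset(order)
    n = table.n
    M = np.zeros((n, n), dtype=float)
    for i in range(n):
        lo = i if mode == "similarity" else i + 1
        for j in range(lo, n):
            try:
                v = func(table.X[i], table.X[j], **measure_kwargs)
            except DegeneratePairError as exc:
                raise DegeneratePairError(
                    f"{key} degenerate for pair ({table.ids[i]}, {table.ids[j]}): {exc}"
                ) from exc
            M[i, j] = M[j, i] = v
    return PairwiseMatrix(M, mode, list(table.ids), has_query=query_index is not None)
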