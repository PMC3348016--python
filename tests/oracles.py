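"""Straight-line brute-force reference implementations.

Everything here is deliberately written as plain nested loops over Python
lists — no vectorization, no reuse of symmetry — so the optimized package
code can be checked against an independent computation path.
"""

import math


def rank_oracle(M, mode, i, exclude=()):
    """Neighbor ranking by full sort: (score, index) key, self excluded."""
    n = len(M)
    cand = [j for j in range(n) if j != i and j not in exclude]
    if mode == "dissimilarity":
        return sorted(cand, key=lambda j: (M[i][j], j))
    return sorted(cand, key=lambda j: (-M[i][j], j))


def blocks_oracle(M, mode, kappa, levels, has_query=False):
    """Per-protein neighbor blocks by sort-and-slice."""
    n = len(M)
    blocks = {}
    for i in range(n):
        exclude = (0,) if has_query and i != 0 else ()
        ranked = rank_oracle(M, mode, i, exclude)
        blocks[i] = [ranked[p * kappa : (p + 1) * kappa] for p in range(levels)]
    return blocks


def context_vector_oracle(M, blocks, i, j, kappa, levels):
    """Quadruple loop over block members for each level."""
    out = []
    for p in range(levels):
        total = 0.0
        for m in blocks[i][p]:
            for nn in blocks[j][p]:
                total += M[m][nn]
        out.append(total / (kappa * kappa))
    return out


def unsupervised_iteration_oracle(M, mode, kappa, levels, has_query=False):
    """One full unsupervised refinement round, no optimizations.

    Contexts, per-pair contextual dissimilarities, the ordered-pair average
    over database proteins (diagonal included), ratio factors clamped to
    [exp(-30), exp(30)], and the multiplicative off-diagonal update are all
    recomputed with independent loops for every ordered pair.
    """
    n = len(M)
    blocks = blocks_oracle(M, mode, kappa, levels, has_query)
    r = [
        [
            sum(context_vector_oracle(M, blocks, i, j, kappa, levels)) / levels
            for j in range(n)
        ]
        for i in range(n)
    ]
    db = list(range(1, n)) if has_query else list(range(n))
    r_bar = sum(r[i][j] for i in db for j in db) / (len(db) ** 2)
    lo, hi = math.exp(-30), math.exp(30)
    new = [[M[i][j] for j in range(n)] for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j:
                delta = min(max(r[i][j] / r_bar, lo), hi)
                new[i][j] = M[i][j] * delta
    return new


def confusion_oracle(ranking, relevant, k):
    """Per-cutoff counts by explicit membership tests."""
    tp = fp = tn = fn = 0
    for pos, item in enumerate(ranking):
        hit = pos < k
        rel = item in relevant
        if hit and rel:
            tp += 1
        elif hit:
            fp += 1
        elif rel:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def auc_concordance_oracle(ranking, relevant):
    """Fraction of (relevant, irrelevant) pairs ranked concordantly.

    Assumes a tie-free ranking (a strict total order of positions).
    """
    rel_pos = [p for p, item in enumerate(ranking) if item in relevant]
    irr_pos = [p for p, item in enumerate(ranking) if item not in relevant]
    concordant = sum(1 for a in rel_pos for b in irr_pos if a < b)
    return concordant / (len(rel_pos) * len(irr_pos))
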