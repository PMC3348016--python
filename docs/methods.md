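# Methods

## Model

`prodis` treats a protein database as a symmetric pairwise score matrix
$D = [d_{ij}]_{(N+1)\times(N+1)}$ (query at index 0, database proteins
$1\ldots N$) in one of two modes: *dissimilarity* (non-negative, zero
diagonal; smaller = closer) or *similarity* (diagonal is the self-score;
larger = closer). Four base measures build such matrices from feature
vectors: cosine similarity, Jaccard index, Tanimoto coefficient
(similarities) and squared Euclidean distance (dissimilarity).

The refinement multiplies every off-diagonal entry by a strictly positive
factor derived from *hierarchical neighbor contexts* and iterates the two
coupled quantities — contexts computed from the matrix, matrix updated from
the contexts — for $T$ rounds. Both the unsupervised ratio factor and the
supervised SVM factor are described in the README; this note records the
decisions behind the implementation.

## Conventions and decisions

**Neighbor ranking.** Nearest = smallest dissimilarity (largest
similarity); ties broken by ascending protein index, everywhere (context
construction, retrieval ranking, leave-one-out), so every ranking is
deterministic and exactly reproducible.

**Sub-context blocks.** Block $p$ of protein $i$ holds the neighbors of
1-based rank $(p-1)\kappa+1 \ldots p\kappa$. Blocks therefore partition the
top $P\kappa$ ranks with no overlap and no rank 0; each block has exactly
$\kappa$ members and never contains $i$ itself.

**Query participation.** The query (index 0) is excluded from database
proteins' candidate neighbor lists by default, keeping database contexts
query-independent; its own context is drawn from the database. A flag
(`include_query_in_context`) enables the alternative.

**Context vector sums.** The level average
$d_{ij}(p) = \kappa^{-2}\sum_{m,n} d_{mn}$ runs over *all* member pairs,
including $m=n$ when blocks overlap (those terms contribute the zero
diagonal). This is the literal formula and it has a real consequence: on a
matrix with *no* contextual structure (constant off-diagonal), tied neighbor
lists make blocks index-prefixes whose overlap varies by pair, so the
factor field is not uniformly 1 and the refinement is not exactly the
identity there — only in the full-context limit $K = N-1$, $P=1$ is the
factor constant (a pure rescaling). Degenerate-input behavior, documented
rather than patched, because the same zero-diagonal terms are what pull
$r_{ij}$ down for pairs with genuinely shared neighborhoods.

**Average $\bar r$.** Taken over all $N^2$ ordered database pairs,
diagonal included ($r_{ii}$ is generally non-zero: a protein's context
compared with itself still averages off-diagonal entries).

**Factors.** Clamped to $[e^{-30}, e^{30}]$: factors stay strictly
positive, zeros stay zero, and repeated multiplicative updates cannot
overflow. In similarity mode the unsupervised ratio uses contextual
*similarities* (more-similar-than-average context ⇒ boost), the symmetric
counterpart of the dissimilarity-mode rule; the supervised factor flips
sign to $\exp(+\tilde y/\sigma)$.

**Pair SVM.** A linear soft-margin SVM (scikit-learn `SVC`,
`kernel="linear"`, default $C=1$, tolerance $10^{-4}$), retrained every
iteration on a balanced sample of up to `pairs_per_class` relevant and
irrelevant pairs drawn without replacement from the labeled database pairs.
The solver runs on standardized vectors and the hyperplane is mapped back
to raw coordinates — raw context dissimilarities sit far from the origin on
arbitrary scales, which stalls margin solvers without changing the
decision function. Sampled pairs are re-ordered canonically by index after
drawing, so the fitted model depends only on the sampled *set*; with an
unbinding budget the sample is exactly the exhaustive enumeration. Pairs
involving the unlabeled query are never training items but always receive
factors.

**Temperature $\sigma$.** Default is adaptive: the standard deviation of
the decision values $\tilde y$ over all off-diagonal pairs in the current
iteration, which keeps exponents $O(1)$ on any data scale; a fixed value
can be supplied.

**Seeding.** One run seed drives a `SeedSequence` whose per-iteration
children seed pair sampling; identical config + seed gives bitwise-identical
refined matrices. Leave-one-out derives one child seed per held-out protein.

**Iterations and drift.** Default $T=3$. Multiplicative updates can drift
the overall matrix scale; an optional renormalization rescales the
off-diagonal mean back to its initial value after each round (default on
for $T>3$, off otherwise; scale does not affect any ranking, so this is a
numerical-hygiene choice, not a modeling one).

**Efficiency.** Level matrices $A_p M A_p^\top$ (with $A_p$ the
$1/\kappa$-normalized block indicator) give all context vectors at once and
are symmetric by construction, so each unordered pair is effectively
computed once; a straight-line nested-loop reference implementation in the
test suite pins this path down to $10^{-10}$. `restrict_to_top` refines
only the query plus its $N'$ nearest initial matches — with $N'=N$ it
reproduces the full run exactly, entrywise.

## Evaluation

Retrieval: hits = top $k$ of the ranking, $k = 1\ldots N$; TPR/FPR,
precision/recall from the per-$k$ confusion counts; AUC by trapezoidal
integration of the (FPR, TPR) polyline anchored at (0,0), which equals the
Mann–Whitney concordant-pair statistic on tie-free rankings.
Classification: leave-one-out — each protein in turn becomes the unlabeled
query at index 0, the refinement (if evaluated) is re-run without its
label, and its class is predicted from the top-ranked neighbor. Accuracy is
the fraction correct; re-running the refinement per held-out protein is
what makes the protocol leakage-free.

## Synthetic data

The generator emulates a classified structure database at desk scale:
$C$ class centers at the vertices of a regular simplex (pairwise center
distance = `separation` × `spread`), members isotropic Gaussian around
centers, optional per-class sizes for imbalance. Defaults — 5 classes, 40
per class, 10 features, separation 3.2 — were calibrated once so the plain
baseline measures land at mean retrieval AUC ≈ 0.77–0.80 (squared
Euclidean and cosine respectively), i.e. hard enough that contextual
refinement has headroom.

What the generator does *not* emulate: real descriptor statistics
(anisotropic, heavy-tailed, correlated features), hub proteins, and the
severe class-size imbalance of fold databases. Passing tests demonstrate
the algorithmic contracts and the direction of the refinement effect under
clean cluster structure, not performance on real protein descriptors.

On this isotropic data the supervised and unsupervised variants are nearly
information-equivalent — the SVM decision value and the context ratio rank
query rows almost identically, because all context-vector levels are highly
correlated — so the measured supervised-over-unsupervised gain is small
(≈ +0.005 mean AUC with cosine similarity at the default settings, vs
≈ +0.02–0.03 for either refinement over the baseline). Data where the
levels carry heterogeneous information (real descriptors) is where the
learned per-level weights can matter.

## Problem sizes

The shipped study runs 20 replicates × 20 held-out queries on 200-protein
databases (≈ 30 s total); leave-one-out studies use 60-protein databases.
These sizes give stable replicate means while keeping the full suite fast;
all of them are plain parameters of the study scripts.

## Known limitations

* The refinement is $O(T(N^2 P + N^2\log N))$ per query plus one SVM fit
  per round — intended for re-ranking candidate sets (see
  `restrict_to_top`), not realtime search over large databases.
* Jaccard on real-valued vectors uses a support threshold (> 0 by default)
  to binarize; this is a convention, configurable, not canonical.
* Cosine of a zero vector returns 0 with a warning by default (strict mode
  raises); Tanimoto of two zero vectors is an error naming the pair.
* Only $k=1$ nearest-neighbor label assignment is implemented for
  leave-one-out; no $k>1$ voting.
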