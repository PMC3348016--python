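# prodis

Supervised contextual dissimilarity learning for protein database retrieval.

## The problem

A protein retrieval system represents each protein (a structure domain, a
sequence, any entity with a numeric descriptor) as a feature vector and ranks
a database against a query by a pairwise score — cosine similarity, Jaccard,
Tanimoto, or squared Euclidean distance. Plain pairwise scores ignore two
things a curated database knows: the *distribution* of the other proteins
(the context), and the *class labels* (e.g. fold assignments) of the database
entries. `prodis` refines any such pairwise measure using both.

## The method

The *context* of protein $x_i$ is its $K$ nearest neighbors $N(i)$ under the
current matrix, split by rank into $P$ *hierarchical sub-contexts*
$N_p(i)$ of size $\kappa$ each ($K = P\kappa$): block 1 holds the nearest
$\kappa$ neighbors, block 2 the next $\kappa$, and so on. For a pair
$(i, j)$ the sub-contextual dissimilarity at level $p$ is the mean pairwise
score between corresponding blocks,

$$d_{ij}(p) = \frac{1}{\kappa^2}\sum_{m\in N_p(i),\,n\in N_p(j)} d_{mn},$$

stacked into the context vector
$\mathbf d_{ij} = [d_{ij}(1)\,\cdots\,d_{ij}(P)]^\top$ with scalar mean
$r_{ij}$. Every pairwise entry is then multiplied by a strictly positive
regularization factor $\delta_{ij}$:

* **Unsupervised (ProDis-ContHC)** — $\delta_{ij} = r_{ij}/\bar r$, the ratio
  of the pair's contextual dissimilarity to the database average
  $\bar r = \frac{1}{N^2}\sum_{i,j} r_{ij}$.
* **Supervised (ProDis-ContSHC)** — database pairs are labeled *relevant*
  ($y=+1$, same class) or *irrelevant* ($y=-1$); a linear soft-margin SVM
  $f(\mathbf d) = \mathbf d\cdot\mathbf w + b$ is trained on a balanced
  sample of pair context vectors, and
  $\delta_{ij} = \exp(-\tilde y_{ij}/\sigma)$ with
  $\tilde y_{ij} = f(\mathbf d_{ij})$ (sign flipped to
  $\exp(+\tilde y_{ij}/\sigma)$ when the base measure is a similarity).

Contexts and the matrix are updated *coherently*: after each multiplicative
update the neighbor contexts are rebuilt from the refined matrix and the
factors re-learned, for $T$ rounds (a fixed-point recursion). The query sits
at matrix index 0, unlabeled: it never enters SVM training but its pairs
receive factors, and the final ranking reads the refined query row.
Rankings are scored by ROC/AUC and precision–recall against the class
labels, and classification by leave-one-out nearest-neighbor accuracy.

## Worked example

```sh
prodis synth --classes 3 --per-class 12 --features 5 --separation 3.0 --seed 42 -o proteins.tsv
prodis build proteins.tsv --measure cosine --query-id p0000 -o base.tsv
prodis refine base.tsv labels.tsv --kappa 3 --levels 2 --iterations 3 \
    --pairs-per-class 50 --seed 1 -o refined.tsv
prodis evaluate base.tsv    labels.tsv --protocol roc --query-label c0 -o base_report.json
prodis evaluate refined.tsv labels.tsv --protocol roc --query-label c0 -o refined_report.json
```

(`labels.tsv` is a two-column `id`/`label` TSV; here taken from the synthetic
table.) The refine step logs one line per round:

```
iteration 1/3: mean factor 1.0094, SVM pairs 100 (44 margin violations)
iteration 2/3: mean factor 1.9632, SVM pairs 100 (22 margin violations)
iteration 3/3: mean factor 3.0844, SVM pairs 100 (36 margin violations)
```

and the two reports show what the refinement bought: the base cosine ranking
of the 35 database proteins places the 11 proteins of the query's class at
AUC **0.9167**; after three supervised contextual rounds the refined ranking
separates them perfectly, AUC **1.0**.

The same flow is available as a library — `build_matrix`,
`hierarchical_context`, `prodis_iterate`, `rank_database`, `roc_and_auc`,
`loo_classification_accuracy` — see the module docstrings.

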