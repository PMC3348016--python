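import math

import numpy as np
import pytest

from conftest import random_dissimilarity
from oracles import unsupervised_iteration_oracle

from prodis import (
    IterationConfig,
    PairModel,
    PairTrainingSet,
    PairwiseMatrix,
    build_matrix,
    build_pair_training_set,
    hierarchical_context,
    prodis_iterate,
    rank_database,
    restrict_to_top,
    supervised_factor,
    train_pair_svm,
    unsupervised_factor,
)
from prodis.regularize import enumerate_pairs
from prodis.synthdata import SynthSpec, generate_clustered


def _constant_matrix(n, c=2.0, has_query=False):
    M = np.full((n, n), c)
    np.fill_diagonal(M, 0.0)
    return PairwiseMatrix(M, "dissimilarity", [f"x{i}" for i in range(n)], has_query)


class TestUnsupervisedFactor:
    def test_average_context_is_neutral(self):
        assert unsupervised_factor(3.7, 3.7) == 1.0

    def test_ratio(self):
        assert unsupervised_factor(4.0, 2.0) == 2.0

    def test_nonpositive_average_errors(self):
        with pytest.raises(ValueError, match="positive"):
            unsupervised_factor(1.0, 0.0)

    def test_zero_ratio_clamped_strictly_positive(self):
        f = unsupervised_factor(0.0, 1.0)
        assert f == pytest.approx(math.exp(-30))
        assert f > 0

    def test_collinear_hand_enumeration(self, collinear_matrix):
        """Points 0,1,3 (squared Euclidean), kappa=1, P=1.

        Contexts: N(a)={b}, N(b)={a}, N(c)={b}; r matrix is
        [[0,1,0],[1,0,1],[0,1,0]] and r_bar = 4/9 over the 9 ordered pairs.
        """
        ctx = hierarchical_context(collinear_matrix, 1, 1)
        from prodis import flat_contextual_dissimilarity

        r = np.array(
            [
                [flat_contextual_dissimilarity(collinear_matrix, ctx, i, j) for j in range(3)]
                for i in range(3)
            ]
        )
        assert np.array_equal(r, [[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        r_bar = r.mean()
        assert r_bar == pytest.approx(4 / 9)
        assert unsupervised_factor(r[0, 1], r_bar) == pytest.approx(9 / 4)
        assert unsupervised_factor(r[0, 2], r_bar) == pytest.approx(math.exp(-30))


class TestPairTrainingSet:
    def _clustered_matrix(self, sizes=(3, 3), seed=0):
        spec = SynthSpec(
            n_classes=len(sizes), n_per_class=list(sizes), n_features=max(2, len(sizes)),
            separation=3.0, seed=seed,
        )
        table = generate_clustered(spec)
        m = build_matrix(table, "sqeuclidean")
        return m, table.labels

    def test_minimal_budget_counts(self):
        m, labels = self._clustered_matrix((2, 2))
        ctx = hierarchical_context(m, 1, 1)
        ts = build_pair_training_set(m, ctx, labels, budget=1, seed=0)
        assert ts.n_relevant == 1 and ts.n_irrelevant == 1

    def test_sampler_never_exceeds_population(self):
        """Pair counts follow the combinatorics of the class sizes."""
        sizes = (4, 3, 2)
        m, labels = self._clustered_matrix(sizes)
        ctx = hierarchical_context(m, 2, 2)
        rel, irr = enumerate_pairs(labels, range(m.n))
        n_rel_expected = sum(s * (s - 1) // 2 for s in sizes)
        n_irr_expected = (
            sum(a * b for i, a in enumerate(sizes) for b in sizes[i + 1:])
        )
        assert len(rel) == n_rel_expected and len(irr) == n_irr_expected
        ts = build_pair_training_set(m, ctx, labels, budget=10**6, seed=1)
        assert ts.n_relevant == n_rel_expected
        assert ts.n_irrelevant == n_irr_expected

    def test_balanced_when_budget_binds(self):
        m, labels = self._clustered_matrix((4, 4))
        ctx = hierarchical_context(m, 2, 2)
        ts = build_pair_training_set(m, ctx, labels, budget=3, seed=5)
        assert ts.n_relevant == ts.n_irrelevant == 3

    def test_seeded_determinism(self):
        m, labels = self._clustered_matrix((4, 4))
        ctx = hierarchical_context(m, 2, 2)
        a = build_pair_training_set(m, ctx, labels, budget=4, seed=42)
        b = build_pair_training_set(m, ctx, labels, budget=4, seed=42)
        assert a.pairs == b.pairs
        assert np.array_equal(a.vectors, b.vectors)
        assert np.array_equal(a.y, b.y)

    def test_relevance_labels_follow_class_labels(self):
        m, labels = self._clustered_matrix((3, 3))
        ctx = hierarchical_context(m, 1, 2)
        ts = build_pair_training_set(m, ctx, labels, budget=100, seed=0)
        for (i, j), y in zip(ts.pairs, ts.y):
            assert i < j
            assert y == (1 if labels[i] == labels[j] else -1)

    def test_query_pairs_never_trained(self):
        m, labels = self._clustered_matrix((3, 3))
        qm, order = m.with_query(0)
        qlabels = [None] + [labels[j] for j in order[1:]]
        ctx = hierarchical_context(qm, 1, 2)
        ts = build_pair_training_set(qm, ctx, qlabels, budget=100, seed=0)
        assert all(i != 0 and j != 0 for i, j in ts.pairs)

    def test_missing_class_errors(self):
        m, labels = self._clustered_matrix((3, 3))
        ctx = hierarchical_context(m, 1, 1)
        same = ["c0"] * len(labels)
        with pytest.raises(ValueError, match="irrelevant"):
            build_pair_training_set(m, ctx, same, budget=1, seed=0)
        distinct = [f"c{i}" for i in range(len(labels))]
        with pytest.raises(ValueError, match="relevant"):
            build_pair_training_set(m, ctx, distinct, budget=1, seed=0)


class TestPairSvm:
    def test_separable_1d(self):
        ts = PairTrainingSet(pairs=[(1, 2), (3, 4)], vectors=[[0.0], [2.0]], y=[1, -1])
        model = train_pair_svm(ts, c_soft=100.0)
        assert model.decision([0.0]) > 0 > model.decision([2.0])

    def test_symmetric_support_points(self):
        ts = PairTrainingSet(pairs=[(1, 2), (3, 4)], vectors=[[-1.0], [1.0]], y=[1, -1])
        model = train_pair_svm(ts, c_soft=100.0)
        assert abs(model.decision([-1.0])) == pytest.approx(abs(model.decision([1.0])), abs=1e-6)

    def test_margin_constraints_on_separable_set(self, rng):
        """On a separable set with large C every y(w.d+b) >= 1 holds."""
        pos = rng.normal([0, 0], 0.3, size=(12, 2))
        neg = rng.normal([4, 4], 0.3, size=(12, 2))
        ts = PairTrainingSet(
            pairs=[(i, i + 100) for i in range(24)],
            vectors=np.vstack([pos, neg]),
            y=[1] * 12 + [-1] * 12,
        )
        model = train_pair_svm(ts, c_soft=1000.0)
        margins = ts.y * (ts.vectors @ model.w + model.b)
        assert np.all(margins >= 1.0 - 1e-3)
        assert model.margin_violations == 0

    def test_single_class_errors(self):
        ts = PairTrainingSet(pairs=[(1, 2), (3, 4)], vectors=[[0.0], [1.0]], y=[1, 1])
        with pytest.raises(ValueError, match="both pair classes"):
            train_pair_svm(ts)


class TestSupervisedFactor:
    def test_boundary_pair_is_neutral(self):
        model = PairModel(w=[0.0, 0.0], b=0.0)
        for sigma in (0.1, 1.0, 10.0):
            assert supervised_factor([5.0, -3.0], model, sigma) == 1.0

    def test_unit_exponent(self):
        model = PairModel(w=[1.0], b=0.0)
        assert supervised_factor([2.0], model, 2.0) == pytest.approx(math.exp(-1))
        assert supervised_factor([2.0], model, 2.0, mode="similarity") == pytest.approx(math.exp(1))

    def test_strictly_decreasing_in_decision_value(self):
        model = PairModel(w=[1.0], b=0.0)
        grid = [supervised_factor([v], model, 1.5) for v in np.linspace(-3, 3, 25)]
        assert all(a > b for a, b in zip(grid, grid[1:]))
        assert all(f > 0 for f in grid)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError, match="sigma"):
            supervised_factor([1.0], PairModel(w=[1.0], b=0.0), 0.0)


class TestProdisIterate:
    def test_uniform_matrix_full_context_gives_constant_factor(self):
        """With the full neighbor set as context (K = N-1, P = 1), a constant
        matrix yields one shared factor for every pair: the update is a pure
        rescaling and the ranking structure is untouched.  (With partial
        contexts the overlap of tied neighbor blocks varies by pair and the
        zero diagonal terms of the block average break exact uniformity.)"""
        m = _constant_matrix(8, c=2.0)
        cfg = IterationConfig(kappa=7, levels=1, iterations=1, supervised=False, renormalize=False)
        out = prodis_iterate(m, config=cfg)
        off = ~np.eye(8, dtype=bool)
        ratios = out.M[off] / m.M[off]
        assert np.allclose(ratios, ratios[0], atol=1e-12)
        cfg_rn = IterationConfig(kappa=7, levels=1, iterations=1, supervised=False, renormalize=True)
        out_rn = prodis_iterate(m, config=cfg_rn)
        assert np.allclose(out_rn.M, m.M, atol=1e-12)

    def test_single_unsupervised_round_matches_hand_enumeration(self, collinear_matrix):
        """T=1 on the 0/1/3 collinear points: factors 9/4, exp(-30), 9/4."""
        cfg = IterationConfig(kappa=1, levels=1, iterations=1, supervised=False, renormalize=False)
        out = prodis_iterate(collinear_matrix, config=cfg)
        expected = np.array(
            [
                [0, 1 * 9 / 4, 9 * math.exp(-30)],
                [1 * 9 / 4, 0, 4 * 9 / 4],
                [9 * math.exp(-30), 4 * 9 / 4, 0],
            ]
        )
        assert np.allclose(out.M, expected, atol=1e-12)

    def test_matches_straight_line_reference(self, rng):
        """Optimized single round equals the no-reuse loop reference."""
        for n in (6, 8, 10):
            for has_query in (False, True):
                m = random_dissimilarity(rng, n, has_query=has_query)
                cfg = IterationConfig(
                    kappa=2, levels=2, iterations=1, supervised=False, renormalize=False
                )
                out = prodis_iterate(m, config=cfg)
                ref = unsupervised_iteration_oracle(m.M.tolist(), m.mode, 2, 2, has_query)
                assert np.allclose(out.M, np.array(ref), atol=1e-10)

    def test_symmetry_and_zero_diagonal_preserved(self, rng):
        table = generate_clustered(SynthSpec(n_classes=3, n_per_class=8, n_features=4, seed=3))
        m = build_matrix(table, "sqeuclidean")
        for supervised in (False, True):
            cfg = IterationConfig(
                kappa=3, levels=2, iterations=4, supervised=supervised,
                pairs_per_class=20, seed=9,
            )
            out = prodis_iterate(m, table.labels, cfg)
            assert np.array_equal(out.M, out.M.T)
            assert np.all(np.diag(out.M) == 0)
            assert np.all(out.M >= 0)

    def test_seeded_determinism(self):
        table = generate_clustered(SynthSpec(n_classes=3, n_per_class=8, n_features=4, seed=3))
        m = build_matrix(table, "sqeuclidean")
        cfg = IterationConfig(kappa=3, levels=2, iterations=2, pairs_per_class=15, seed=77)
        a = prodis_iterate(m, table.labels, cfg)
        b = prodis_iterate(m, table.labels, cfg)
        assert np.array_equal(a.M, b.M)

    def test_supervised_requires_labels(self):
        m = _constant_matrix(8)
        with pytest.raises(ValueError, match="labels"):
            prodis_iterate(m, config=IterationConfig(kappa=2, levels=2))

    def test_query_must_be_unlabeled(self):
        m = _constant_matrix(6, has_query=True)
        with pytest.raises(ValueError, match="unlabeled"):
            prodis_iterate(m, ["c0"] * 6, IterationConfig(kappa=1, levels=1, supervised=False))

    def test_history_diagnostics(self):
        table = generate_clustered(SynthSpec(n_classes=2, n_per_class=6, n_features=3, seed=1))
        m = build_matrix(table, "sqeuclidean")
        history = []
        cfg = IterationConfig(kappa=2, levels=2, iterations=3, pairs_per_class=10, seed=0)
        prodis_iterate(m, table.labels, cfg, history=history)
        assert [h.iteration for h in history] == [1, 2, 3]
        assert all(h.mean_factor > 0 for h in history)
        assert all(h.training_size == 20 for h in history)


class TestRestrictAndRank:
    def _query_matrix(self, rng, n=8):
        return random_dissimilarity(rng, n, has_query=True)

    def test_full_restriction_is_identity(self, rng):
        m = self._query_matrix(rng)
        sub, keep = restrict_to_top(m, m.n - 1)
        assert np.array_equal(sub.M, m.M)
        assert np.array_equal(keep, np.arange(m.n))

    def test_selects_nearest_by_rank(self, rng):
        m = self._query_matrix(rng, n=6)
        sub, keep = restrict_to_top(m, 2)
        from prodis import rank_neighbors

        nearest = set(rank_neighbors(m, 0)[:2])
        assert set(keep[1:]) == nearest
        assert sub.n == 3 and sub.has_query

    def test_refine_on_full_restriction_equals_full_run(self, rng):
        table = generate_clustered(SynthSpec(n_classes=2, n_per_class=6, n_features=3, seed=8))
        m = build_matrix(table, "sqeuclidean", query_index=0)
        labels = [None] + table.labels[1:]
        sub, keep = restrict_to_top(m, m.n - 1)
        cfg = IterationConfig(kappa=2, levels=2, iterations=2, pairs_per_class=10, seed=4)
        full = prodis_iterate(m, labels, cfg)
        restricted = prodis_iterate(sub, labels, cfg)
        assert np.array_equal(full.M, restricted.M)

    def test_rank_database_sorts_query_row(self):
        M = np.zeros((4, 4))
        M[0, 1:] = M[1:, 0] = [3, 1, 2]
        M[1, 2] = M[2, 1] = 5
        M[1, 3] = M[3, 1] = 5
        M[2, 3] = M[3, 2] = 5
        m = PairwiseMatrix(M, "dissimilarity", list("qabc"), has_query=True)
        assert list(rank_database(m)) == [2, 3, 1]

    def test_rank_database_similarity_descending(self):
        M = np.array([[2.0, 0.2, 0.9], [0.2, 2.0, 0.5], [0.9, 0.5, 2.0]])
        m = PairwiseMatrix(M, "similarity", list("qab"), has_query=True)
        assert list(rank_database(m)) == [2, 1]

    def test_rank_matches_oracle_sort(self, rng):
        m = self._query_matrix(rng, n=10)
        expected = sorted(range(1, 10), key=lambda j: (m.M[0, j], j))
        assert list(rank_database(m)) == expected
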