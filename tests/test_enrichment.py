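import numpy as np
import pytest

from stea import (
    EnrichmentConfig,
    EnrichmentMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    annotate,
    enrichment_score,
    rank_transform,
    score_all,
)


def es_bruteforce(ranks, in_set, alpha):
    """Literal evaluation of the two-CDF enrichment formula (test oracle)."""
    ranks = np.asarray(ranks, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    n = ranks.size
    order = np.argsort(-ranks, kind="stable")
    w = [ranks[order[k]] ** alpha for k in range(n)]
    denom_pos = sum(w[k] for k in range(n) if in_set[order[k]])
    n_out = sum(1 for k in range(n) if not in_set[order[k]])
    total = 0.0
    for j in range(n):
        p_pos = sum(w[k] for k in range(j + 1) if in_set[order[k]]) / denom_pos
        p_neg = sum(1 for k in range(j + 1) if not in_set[order[k]]) / n_out
        total += p_pos - p_neg
    return total / n


class TestRankTransform:
    def test_strictly_decreasing_input(self):
        p = rank_transform(np.array([9.0, 7.0, 4.0, 1.0]))
        np.testing.assert_array_equal(p.ranks, [4, 3, 2, 1])
        np.testing.assert_array_equal(p.order, [0, 1, 2, 3])

    def test_full_tie_average(self):
        p = rank_transform(np.full(5, 2.0))
        np.testing.assert_array_equal(p.ranks, np.full(5, 3.0))

    def test_hand_tie_oracle(self):
        p = rank_transform(np.array([5.0, 5.0, 1.0]))
        np.testing.assert_array_equal(p.ranks, [2.5, 2.5, 1.0])
        # descending order breaks the tie by input gene index
        np.testing.assert_array_equal(p.order, [0, 1, 2])

    def test_ordinal_ties(self):
        # rank 1 is the lowest value; ordinal breaks the 5.0 tie by position
        p = rank_transform(np.array([5.0, 5.0, 1.0]), tie_method="ordinal")
        np.testing.assert_array_equal(p.ranks, [2, 3, 1])


class TestEnrichmentScore:
    def test_top_two_of_four_alpha0(self):
        # hand CDFs: P+=(0.5,1,1,1), P-=(0,0,0.5,1) -> mean diff 0.5
        profile = rank_transform(np.array([4.0, 3.0, 2.0, 1.0]))
        es = enrichment_score(
            profile, [True, True, False, False], EnrichmentConfig(alpha=0.0)
        )
        assert es == pytest.approx(0.5, abs=1e-12)

    def test_bottom_two_of_four_alpha0(self):
        profile = rank_transform(np.array([4.0, 3.0, 2.0, 1.0]))
        es = enrichment_score(
            profile, [False, False, True, True], EnrichmentConfig(alpha=0.0)
        )
        assert es == pytest.approx(-0.5, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 50, 500])
    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_singleton_top_gene_scores_half(self, n, alpha):
        # closed form: 1 - (1/N) sum_j (j-1)/(N-1) = 0.5 for every N, alpha
        expr = np.linspace(n, 1, n)
        in_set = np.zeros(n, dtype=bool)
        in_set[0] = True
        es = enrichment_score(
            rank_transform(expr), in_set, EnrichmentConfig(alpha=alpha)
        )
        assert es == pytest.approx(0.5, abs=1e-12)

    def test_oracle_equivalence_sweep(self, rng):
        """1000 random (profile, set, alpha) cases vs brute force at 1e-12."""
        config_cache = {}
        for _ in range(1000):
            n = rng.integers(3, 51)
            expr = rng.gamma(1.0, 2.0, n).round(1)  # induce some ties
            n_set = rng.integers(1, n)
            in_set = np.zeros(n, dtype=bool)
            in_set[rng.choice(n, n_set, replace=False)] = True
            alpha = float(rng.uniform(0.0, 1.0))
            profile = rank_transform(expr)
            got = enrichment_score(
                profile, in_set, EnrichmentConfig(alpha=alpha)
            )
            assert abs(got - es_bruteforce(profile.ranks, in_set, alpha)) < 1e-12

    def test_alpha0_matches_unweighted_cdf(self, rng):
        # separate unweighted route: P+ is the plain in-set empirical CDF
        n = 30
        expr = rng.random(n)
        in_set = np.zeros(n, dtype=bool)
        in_set[rng.choice(n, 10, replace=False)] = True
        profile = rank_transform(expr)
        mask = in_set[profile.order]
        pos = np.cumsum(mask) / mask.sum()
        neg = np.cumsum(~mask) / (n - mask.sum())
        expected = np.mean(pos - neg)
        got = enrichment_score(profile, in_set, EnrichmentConfig(alpha=0.0))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_rank_swap(self):
        """Swapping an in-set gene upward in rank never decreases ES."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = 20
            expr = rng.permutation(np.arange(1.0, n + 1))
            in_set = np.zeros(n, dtype=bool)
            in_set[rng.choice(n, 6, replace=False)] = True
            config = EnrichmentConfig(alpha=0.25)
            base = enrichment_score(rank_transform(expr), in_set, config)
            # move one in-set gene to the top rank by swapping values
            i = int(np.flatnonzero(in_set)[0])
            j = int(np.argmax(expr))
            if in_set[j]:
                continue
            expr2 = expr.copy()
            expr2[i], expr2[j] = expr2[j], expr2[i]
            boosted = enrichment_score(rank_transform(expr2), in_set, config)
            assert boosted >= base - 1e-12

    def test_random_set_mean_near_zero_unweighted(self, rng):
        """Unweighted ES of a random set over random profiles averages to ~0.

        The zero-mean null holds for alpha = 0, where in-set and background
        CDFs are exchangeable; rank-power weighting (alpha > 0) adds a small
        positive offset common to every set, which cancels at the argmax.
        """
        n, reps = 40, 2000
        scores = np.empty(reps)
        for r in range(reps):
            expr = rng.random(n)
            in_set = np.zeros(n, dtype=bool)
            in_set[rng.choice(n, 8, replace=False)] = True
            scores[r] = enrichment_score(
                rank_transform(expr), in_set, EnrichmentConfig(alpha=0.0)
            )
        se = scores.std(ddof=1) / np.sqrt(reps)
        assert abs(scores.mean()) < 3 * se

    def test_degenerate_sets_rejected(self):
        profile = rank_transform(np.array([3.0, 2.0, 1.0]))
        with pytest.raises(ValueError, match="intersect"):
            enrichment_score(profile, [False, False, False])
        with pytest.raises(ValueError, match="background"):
            enrichment_score(profile, [True, True, True])

    def test_scores_within_unit_interval(self, rng):
        for _ in range(200):
            n = rng.integers(3, 40)
            expr = rng.random(n)
            k = rng.integers(1, n)
            in_set = np.zeros(n, dtype=bool)
            in_set[rng.choice(n, k, replace=False)] = True
            es = enrichment_score(rank_transform(expr), in_set)
            assert -1.0 <= es <= 1.0


class TestScoreAll:
    def test_single_set_single_spot_composition(self):
        m = ExpressionMatrix(
            np.array([[3.0], [2.0], [1.0]]), ["a", "b", "c"], ["s1"]
        )
        sets = GeneSetCollection({"t": ["a"]})
        es = score_all(m, sets, normalize_expr=False)
        profile = rank_transform(m.values[:, 0])
        expected = enrichment_score(profile, [True, False, False])
        assert es.values[0, 0] == pytest.approx(expected, abs=1e-15)

    def test_duplicated_spot_scores_identically(self, tiny_matrix):
        values = np.hstack([tiny_matrix.values, tiny_matrix.values[:, :1]])
        m = ExpressionMatrix(
            values, tiny_matrix.gene_ids, tiny_matrix.spot_ids + ["s1copy"]
        )
        es = score_all(m, GeneSetCollection({"t": ["g1"]}))
        assert es.values[0, -1] == pytest.approx(es.values[0, 0], abs=1e-15)

    def test_gene_order_invariance(self, rng):
        n_genes, n_spots = 40, 10
        values = rng.random((n_genes, n_spots))
        genes = [f"g{i}" for i in range(n_genes)]
        m = ExpressionMatrix(values, genes, [f"s{j}" for j in range(n_spots)])
        sets = GeneSetCollection({"t": genes[:7]})
        perm = rng.permutation(n_genes)
        m2 = ExpressionMatrix(values[perm], [genes[i] for i in perm], m.spot_ids)
        es1 = score_all(m, sets)
        es2 = score_all(m2, sets)
        np.testing.assert_allclose(es1.values, es2.values, atol=1e-12)

    def test_bruteforce_sweep_over_matrix(self, rng):
        n_genes, n_spots = 25, 100
        values = rng.gamma(1.0, 3.0, (n_genes, n_spots)).round(1)
        genes = [f"g{i}" for i in range(n_genes)]
        m = ExpressionMatrix(values, genes, [f"s{j}" for j in range(n_spots)])
        sets = GeneSetCollection(
            {f"set{k}": list(rng.choice(genes, 6, replace=False)) for k in range(3)}
        )
        es = score_all(m, sets, normalize_expr=False)
        for i, (name, members) in enumerate(sets):
            in_set = np.isin(genes, members)
            for j in rng.choice(n_spots, 10, replace=False):
                profile = rank_transform(values[:, j])
                expected = es_bruteforce(profile.ranks, in_set, 0.25)
                assert abs(es.values[i, j] - expected) < 1e-12

    def test_minmax_normalization_preserves_argmax(self, rng):
        values = rng.random((20, 15))
        genes = [f"g{i}" for i in range(20)]
        m = ExpressionMatrix(values, genes, [f"s{j}" for j in range(15)])
        sets = GeneSetCollection({"a": genes[:5], "b": genes[5:10]})
        raw = score_all(m, sets)
        mm = score_all(m, sets, config=EnrichmentConfig(normalize="minmax"))
        assert mm.values.min() >= 0.0 and mm.values.max() <= 1.0
        for row_raw, row_mm in zip(raw.values, mm.values):
            assert np.argmax(row_raw) == np.argmax(row_mm)


class TestAnnotate:
    def test_argmax_label_and_margin(self):
        es = EnrichmentMatrix(
            np.array([[0.4], [0.1]]), ["A", "B"], ["s1"]
        )
        res = annotate(es)
        assert res.labels == ["A"]
        assert res.margin[0] == pytest.approx(0.3)

    def test_single_set_margin_zero(self):
        es = EnrichmentMatrix(np.array([[0.2, 0.7]]), ["only"], ["s1", "s2"])
        res = annotate(es)
        assert res.labels == ["only", "only"]
        np.testing.assert_array_equal(res.margin, [0.0, 0.0])

    def test_tie_broken_by_name_order(self):
        es = EnrichmentMatrix(
            np.array([[0.5], [0.5]]), ["zeta", "alpha"], ["s1"]
        )
        assert annotate(es).labels == ["alpha"]

    def test_recovers_truth_on_separated_dataset(self, small_dataset):
        from stea import accuracy, score_all

        es = score_all(
            small_dataset.matrix, small_dataset.marker_map,
            config=EnrichmentConfig(normalize="minmax"),
        )
        res = annotate(es)
        assert accuracy(res.labels, small_dataset.truth) >= 0.90
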