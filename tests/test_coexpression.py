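"""PCA basis, PC-space correlation, and the stability statistic."""

import numpy as np
import pytest
from scipy import stats

from coexstab.coexpression import (
    CoexpressionError,
    DimensionalityError,
    ExpressionMatrix,
    fit_pca,
    pairwise_profiles,
    pc_correlation,
    spearman_rank_correlation,
    stability_from_correlations,
    stability_profile,
)


def random_expr(n_genes, n_samples, seed=0):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        rng.normal(0, 1, (n_genes, n_samples)),
        [f"g{i}" for i in range(n_genes)],
        [f"s{j}" for j in range(n_samples)],
    )


class TestExpressionMatrix:
    def test_rejects_too_small(self):
        with pytest.raises(DimensionalityError):
            ExpressionMatrix(np.ones((1, 5)), ["g0"], [f"s{j}" for j in range(5)])

    def test_rejects_nonfinite_and_duplicates(self):
        with pytest.raises(CoexpressionError):
            ExpressionMatrix(np.array([[1.0, np.nan], [0.0, 1.0]]), ["a", "b"], ["s0", "s1"])
        with pytest.raises(CoexpressionError):
            ExpressionMatrix(np.ones((2, 2)), ["a", "a"], ["s0", "s1"])

    def test_zero_variance_genes_flagged(self):
        expr = random_expr(4, 6)
        expr.values[2] = 3.14
        assert ExpressionMatrix(expr.values, expr.gene_ids, expr.sample_ids).zero_variance_genes() == ["g2"]

    def test_tsv_round_trip(self, tmp_path, small_expr):
        path = tmp_path / "expr.tsv"
        small_expr.to_tsv(path, comments=["seed=1"])
        back = ExpressionMatrix.from_tsv(path)
        assert back.gene_ids == small_expr.gene_ids
        assert back.sample_ids == small_expr.sample_ids
        np.testing.assert_allclose(back.values, small_expr.values, atol=1e-5)


class TestFitPca:
    def test_full_threshold_reconstructs_centered_matrix(self):
        expr = random_expr(10, 6, seed=3)
        basis = fit_pca(expr, variance_threshold=1.0)
        centered = expr.values - expr.values.mean(axis=0)
        assert basis.K == np.linalg.matrix_rank(centered)
        residual = np.linalg.norm(basis.scores @ basis.components - centered)
        assert residual < 1e-8 * np.linalg.norm(centered)

    def test_rank_one_matrix_clamps_to_two_components(self):
        # all genes scalar multiples of one profile
        rng = np.random.default_rng(5)
        profile = rng.normal(0, 1, 7)
        coefs = rng.uniform(0.5, 2.0, 9)
        values = np.outer(coefs, profile)
        expr = ExpressionMatrix(values, [f"g{i}" for i in range(9)], [f"s{j}" for j in range(7)])
        basis = fit_pca(expr, variance_threshold=0.8)
        assert basis.K == 2
        # oracle: leading variance fraction from a direct eigendecomposition
        centered = values - values.mean(axis=0)
        eig = np.linalg.eigvalsh(centered.T @ centered)[::-1]
        assert eig[0] / eig.sum() >= 0.999
        assert basis.explained_fraction[0] >= 0.999

    def test_threshold_is_the_defining_property_of_k(self):
        expr = random_expr(60, 30, seed=7)
        basis = fit_pca(expr, variance_threshold=0.8)
        pca_full = fit_pca(expr, variance_threshold=1.0)
        cum = np.cumsum(pca_full.explained_fraction)
        assert cum[basis.K - 1] >= 0.8
        assert cum[basis.K - 2] < 0.8

    def test_invalid_threshold_rejected(self):
        with pytest.raises(CoexpressionError):
            fit_pca(random_expr(5, 4), variance_threshold=0.0)


class TestPcCorrelation:
    def test_self_correlation_is_one(self, small_expr):
        basis = fit_pca(small_expr, 1.0)
        for drop in range(basis.K - 1):
            assert pc_correlation(basis, "g0", "g0", drop) == pytest.approx(1.0)

    def test_duplicate_and_negated_profiles(self, small_expr):
        basis = fit_pca(small_expr, 1.0)
        assert pc_correlation(basis, "g0", "g1") == pytest.approx(1.0)
        assert pc_correlation(basis, "g0", "g2") == pytest.approx(-1.0)

    def test_symmetry(self, small_expr):
        basis = fit_pca(small_expr, 1.0)
        assert pc_correlation(basis, "g3", "g4") == pytest.approx(
            pc_correlation(basis, "g4", "g3")
        )

    def test_matches_bruteforce_on_scores_and_profiles(self):
        expr = random_expr(6, 5, seed=11)
        basis = fit_pca(expr, 1.0)
        centered = expr.values - expr.values.mean(axis=0)
        for a, b in [("g0", "g3"), ("g1", "g4"), ("g2", "g5")]:
            ia, ib = expr.gene_ids.index(a), expr.gene_ids.index(b)
            # brute-force on independently extracted score columns 2..K
            x, y = basis.scores[ia, 1:], basis.scores[ib, 1:]
            expected = (x @ y) / np.sqrt((x @ x) * (y @ y))
            assert pc_correlation(basis, a, b, drop_top=1) == pytest.approx(expected, abs=1e-12)
            # full-basis value equals the profile-space correlation,
            # computed without any PCA at all
            u, v = centered[ia], centered[ib]
            profile_cor = (u @ v) / np.sqrt((u @ u) * (v @ v))
            assert pc_correlation(basis, a, b, drop_top=0) == pytest.approx(profile_cor, abs=1e-10)

    def test_sign_flip_of_a_component_leaves_correlations_unchanged(self):
        expr = random_expr(20, 10, seed=13)
        basis = fit_pca(expr, 1.0)
        before = [pc_correlation(basis, "g0", "g1", d) for d in range(basis.K - 1)]
        basis.scores[:, 2] *= -1.0
        basis.components[2] *= -1.0
        after = [pc_correlation(basis, "g0", "g1", d) for d in range(basis.K - 1)]
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_too_few_remaining_components(self, small_expr):
        basis = fit_pca(small_expr, 1.0)
        with pytest.raises(DimensionalityError):
            pc_correlation(basis, "g0", "g1", drop_top=basis.K - 1)

    def test_unknown_gene(self, small_expr):
        basis = fit_pca(small_expr, 1.0)
        with pytest.raises(KeyError):
            pc_correlation(basis, "g0", "nope")


class TestStability:
    def test_duplicated_profiles_give_unit_stability(self):
        rng = np.random.default_rng(17)
        values = rng.normal(0, 1, (30, 20))
        values[1] = values[0]
        expr = ExpressionMatrix(values, [f"g{i}" for i in range(30)], [f"s{j}" for j in range(20)])
        basis = fit_pca(expr, 1.0)
        prof = stability_profile(basis, "g0", "g1", N=10)
        np.testing.assert_allclose(prof.cor, 1.0, atol=1e-12)
        assert prof.stability == pytest.approx(1.0)
        assert prof.cor_max == pytest.approx(1.0)

    def test_formula_on_constructed_vector(self):
        cor = [0.9] + [0.1] * 10
        # independent recomputation of the statistic
        expected = (0.9 + 10 * 0.1) / 11 / 0.9
        assert stability_from_correlations(cor) == pytest.approx(expected, abs=1e-12)
        assert stability_from_correlations(cor) == pytest.approx(0.1919, abs=5e-5)

    def test_equal_positive_correlations_give_exactly_one(self):
        assert stability_from_correlations([0.4] * 11) == pytest.approx(1.0)

    def test_requires_enough_components(self, small_expr):
        basis = fit_pca(small_expr, 1.0)
        with pytest.raises(DimensionalityError, match="lower N or raise variance_threshold"):
            stability_profile(basis, "g0", "g3", N=10)


class TestPairwiseProfiles:
    def test_cor0_filter_boundary_and_tally(self):
        expr = random_expr(40, 25, seed=19)
        basis = fit_pca(expr, 1.0)
        pairs = [(f"g{i}", f"g{i + 1}") for i in range(0, 38, 2)]
        res = pairwise_profiles(basis, pairs, min_cor0=0.2, N=10)
        assert res.n_retained + res.n_below_min_cor + res.n_degenerate == len(pairs)
        for p in res.profiles:
            assert p.cor_0 >= 0.2  # pairs at exactly the threshold are retained
        # every excluded pair is genuinely below the threshold
        retained = {p.pair for p in res.profiles}
        for a, b in pairs:
            if tuple(sorted((a, b))) not in retained:
                assert pc_correlation(basis, a, b) < 0.2

    def test_empty_pair_list(self, small_expr):
        basis = fit_pca(small_expr, 1.0)
        res = pairwise_profiles(basis, [])
        assert res.profiles == [] and res.n_below_min_cor == 0

    def test_stability_bounded_by_one_for_retained_pairs(self):
        expr = random_expr(60, 40, seed=23)
        basis = fit_pca(expr, 1.0)
        pairs = [(f"g{i}", f"g{j}") for i in range(20) for j in range(i + 1, 20)]
        res = pairwise_profiles(basis, pairs, min_cor0=0.0, N=10)
        for p in res.profiles:
            if p.cor_max > 0:
                assert p.stability <= 1.0 + 1e-12


class TestSpearman:
    def test_perfect_and_reversed(self):
        rho, _ = spearman_rank_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rank_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_tied_values_match_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        # hand mid-ranks: the tied 2.0s share rank (2+3)/2
        rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0, 6.0])
        ry = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, p = spearman_rank_correlation(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)
        assert 0 < p <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(CoexpressionError):
            spearman_rank_correlation([1, 1, 1, 1], [1, 2, 3, 4])
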