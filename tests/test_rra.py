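import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crisprank.rra import (
    AlphaConfig,
    aggregate_groups,
    alpha_select,
    beta_order_pvalues,
    bh_fdr,
    gene_pvalues,
    gene_test,
    good_prefix_length,
    permutation_null,
    rho_score,
)

from .conftest import analysed_null_screen


class TestBetaOrderPvalues:
    def test_single_percentile_is_uniform(self):
        """Beta(1,1) is Uniform(0,1), so p_1 = u for n = 1."""
        assert beta_order_pvalues(np.array([0.1]))[0] == pytest.approx(0.1)

    def test_two_percentile_closed_form(self):
        """n=2: P(min <= u) = 1-(1-u)^2 and P(max <= u) = u^2."""
        p = beta_order_pvalues(np.array([0.1, 0.5]))
        assert p[0] == pytest.approx(1 - 0.9**2)
        assert p[1] == pytest.approx(0.25)

    def test_matches_monte_carlo_order_statistics(self):
        """For n=5 random percentiles, each p_k agrees with the fraction of
        simulated uniform order statistics below u_k within 3 SEs."""
        rng = np.random.default_rng(123)
        u = np.sort(rng.uniform(size=5))
        p = beta_order_pvalues(u)
        draws = np.sort(rng.uniform(size=(200_000, 5)), axis=1)
        mc = (draws <= u[None, :]).mean(axis=0)
        se = np.sqrt(p * (1 - p) / draws.shape[0])
        assert (np.abs(mc - p) <= 3 * se + 1e-12).all()

    def test_contract_violations(self):
        with pytest.raises(ValueError, match="sorted"):
            beta_order_pvalues(np.array([0.5, 0.1]))
        with pytest.raises(ValueError, match="0, 1"):
            beta_order_pvalues(np.array([0.0, 0.5]))


class TestAlphaSelect:
    def test_threshold_rule(self):
        """p=(0.01, 0.2, 0.04) against threshold 0.05 -> (good, bad, good)."""
        p = np.array([0.01, 0.2, 0.04])
        ranks = np.array([1, 3, 2])  # ranked ascending by p
        good = alpha_select(p, ranks, m=3, cfg=AlphaConfig())
        assert good.tolist() == [True, False, True]
        assert good_prefix_length(good, ranks) == 2

    def test_nothing_passes(self):
        good = alpha_select(np.array([0.5, 0.9]), np.array([1, 2]), 2, AlphaConfig())
        assert not good.any()

    def test_degenerate_classic_rra(self):
        cfg = AlphaConfig(p_threshold=1.0, alpha_percent=1.0)
        good = alpha_select(np.array([0.99, 0.5]), np.array([2, 1]), 2, cfg)
        assert good.all()

    def test_alpha_fraction_caps_selection(self):
        cfg = AlphaConfig(p_threshold=0.05, alpha_percent=0.25)
        p = np.array([0.01, 0.02, 0.03, 0.5])
        ranks = np.array([1, 2, 3, 4])
        assert alpha_select(p, ranks, 4, cfg).tolist() == [True, False, False, False]

    def test_non_prefix_flags_rejected(self):
        with pytest.raises(ValueError, match="prefix"):
            good_prefix_length(np.array([True, False, True]), np.array([1, 2, 3]))


class TestRhoScore:
    def test_min_over_good_prefix(self):
        u = np.array([0.1, 0.5])
        assert rho_score(u, 2) == pytest.approx(0.19)
        assert rho_score(u, 1) == pytest.approx(0.19)

    def test_empty_selection_scores_one(self):
        assert rho_score(np.array([0.2, 0.3]), 0) == 1.0

    def test_j_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            rho_score(np.array([0.1]), 2)

    def test_insignificant_tail_does_not_matter(self):
        """Percentiles beyond the good prefix cannot move rho."""
        a = rho_score(np.array([0.01, 0.04, 0.5, 0.6]), 2)
        b = rho_score(np.array([0.01, 0.04, 0.9, 0.99]), 2)
        assert a == b

    def test_improving_a_good_percentile_never_hurts(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            u = np.sort(rng.uniform(size=6))
            j = rng.integers(1, 7)
            better = u.copy()
            better[0] *= rng.uniform()
            assert rho_score(np.sort(better), j) <= rho_score(u, j) + 1e-15


class TestPermutationNull:
    def test_uniform_for_single_sgrna_genes(self):
        """With everything selected and n=1, rho is the bare percentile,
        uniform on {1/M, ..., 1}."""
        m = 1000
        cfg = AlphaConfig(p_threshold=1.0, alpha_percent=1.0, num_permutations=100_000, seed=9)
        null = permutation_null([1], m, cfg, n_good_prefix=m)
        d = stats.kstest(null[1], "uniform").statistic
        assert d < 0.01

    def test_seed_reproducibility(self):
        cfg = AlphaConfig(num_permutations=500, seed=4)
        a = permutation_null([3, 5], 200, cfg, 20)
        b = permutation_null([3, 5], 200, cfg, 20)
        for n in (3, 5):
            assert np.array_equal(a[n], b[n])

    def test_single_gene_covering_everything_is_constant(self):
        cfg = AlphaConfig(num_permutations=50, seed=1)
        null = permutation_null([10], 10, cfg, 5)
        assert np.allclose(null[10], null[10][0])


class TestGenePvalues:
    def test_boundaries(self):
        null = {2: np.sort(np.linspace(0.01, 1.0, 99))}
        assert gene_pvalues({"g": (2, 0.001)}, null)["g"] == pytest.approx(1 / 100)
        assert gene_pvalues({"g": (2, 1.0)}, null)["g"] == 1.0

    def test_missing_stratum(self):
        with pytest.raises(KeyError):
            gene_pvalues({"g": (3, 0.5)}, {2: np.array([0.5])})

    def test_null_screen_classic_rra_pvalues_uniform(self):
        """On a no-selection screen scored without alpha-selection the gene
        permutation p-values are approximately Uniform(0,1)."""
        *_, res = analysed_null_screen(seed=17)
        cfg = AlphaConfig(p_threshold=1.0, alpha_percent=1.0, seed=17)
        genes = gene_test(res, cfg, "neg")
        assert stats.kstest(genes["p"], "uniform").statistic < 0.05


class TestBH:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_pvalue(self):
        assert bh_fdr(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_matches_step_up_oracle(self):
        """Agreement with a hand-rolled BH step-up on random vectors."""
        rng = np.random.default_rng(21)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 30))
            q = bh_fdr(p)
            n = p.size
            order = np.argsort(p, kind="mergesort")
            scaled = p[order] * n / np.arange(1, n + 1)
            expected = np.minimum.accumulate(scaled[::-1])[::-1]
            expected = np.minimum(expected, 1.0)
            oracle = np.empty(n)
            oracle[order] = expected
            np.testing.assert_allclose(q, oracle, atol=1e-12)

    def test_monotone_in_sorted_pvalues(self):
        rng = np.random.default_rng(2)
        p = np.sort(rng.uniform(size=40))
        assert (np.diff(bh_fdr(p)) >= -1e-15).all()


class TestGeneTest:
    def test_top_ranked_gene_block_wins(self):
        """A gene whose sgRNAs occupy ranks 1..n gets the smallest
        attainable permutation p and overall rank 1."""
        m, n = 200, 4
        ranks = {f"G{i}": list(range(i * n + 1, (i + 1) * n + 1)) for i in range(m // n)}
        cfg = AlphaConfig(num_permutations=2000, seed=3)
        df = aggregate_groups(ranks, m, n_good_prefix=10, cfg=cfg)
        assert df.iloc[0]["group"] == "G0"
        assert df.iloc[0]["rank"] == 1
        assert df.iloc[0]["p"] == df["p"].min()

    def test_null_screen_specificity(self):
        """No-selection screen: at most 5% of genes reach FDR < 0.25."""
        *_, res = analysed_null_screen(seed=23)
        for direction in ("neg", "pos"):
            genes = gene_test(res, AlphaConfig(seed=23), direction)
            assert (genes["fdr"] < 0.25).mean() <= 0.05

    def test_spiked_genes_recovered(self, spiked_screen):
        truth, genes = spiked_screen
        from crisprank.simulator import evaluate_recovery

        assert evaluate_recovery(genes, truth, top_k=40, label="neg") >= 0.8

    def test_deterministic_given_seed(self):
        *_, res = analysed_null_screen(seed=29, n_genes=50)
        cfg = AlphaConfig(seed=7)
        a = gene_test(res, cfg, "neg")
        b = gene_test(res, cfg, "neg")
        pd.testing.assert_frame_equal(a, b)

    def test_results_well_formed(self):
        *_, res = analysed_null_screen(seed=31, n_genes=50)
        df = gene_test(res, AlphaConfig(seed=1), "pos")
        assert (df["j"] <= df["n"]).all()
        assert ((df["rho"] > 0) & (df["rho"] <= 1)).all()
        assert ((df["p"] > 0) & (df["p"] <= 1)).all()
        assert ((df["fdr"] >= 0) & (df["fdr"] <= 1)).all()
        assert (df.loc[df["j"] == 0, "rho"] == 1.0).all()
        assert sorted(df["rank"]) == list(range(1, len(df) + 1))
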