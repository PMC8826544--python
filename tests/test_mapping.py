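"""Association engine vs explicit per-pair regression oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nqtl.mapping import (
    bh_fdr,
    empirical_fdr,
    linear_stats,
    maf_filter,
    manhattan_summary,
    map_anova,
    map_linear,
    qq_summary,
    residualize,
)
from nqtl.matrixio import CovariateMatrix, GenotypeMatrix, SampleMatrix

from conftest import make_expression, make_genotypes


def _mat(values, prefix="t"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return SampleMatrix([f"{prefix}{i}" for i in range(values.shape[0])],
                        [f"s{j}" for j in range(values.shape[1])], values)


def ols_fit(y, X):
    """Oracle: explicit full-design OLS with classic t statistics."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t = beta / np.sqrt(np.diag(cov))
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta, t, p


class TestResidualize:
    def test_no_covariates_is_centering(self):
        np.testing.assert_allclose(residualize(np.array([1.0, 2.0, 3.0])),
                                   [-1.0, 0.0, 1.0], atol=1e-14)

    def test_row_equal_to_covariate_gives_zero(self):
        cov = np.array([[1.0, 3.0, 2.0, 5.0]])
        np.testing.assert_allclose(residualize(cov.copy(), cov), np.zeros((1, 4)),
                                   atol=1e-12)

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.standard_normal((5, 20))
        cov = rng.standard_normal((2, 20))
        R = residualize(X, cov)
        # oracle: per-row least-squares fit on [1, cov]
        D = np.column_stack([np.ones(20), cov.T])
        for i in range(5):
            beta, *_ = np.linalg.lstsq(D, X[i], rcond=None)
            np.testing.assert_allclose(R[i], X[i] - D @ beta, atol=1e-10)
        assert np.abs(R @ D).max() < 1e-10

    def test_rank_deficient_covariates_named(self, rng):
        cov = CovariateMatrix(["c0", "c1"], [f"s{j}" for j in range(6)],
                              np.vstack([np.ones(6), 2 * np.ones(6)]))
        with pytest.raises(ValueError, match="c0|c1"):
            residualize(np.zeros((1, 6)), cov)


class TestMapLinear:
    def test_perfect_association(self, rng):
        g = make_genotypes(rng, n_snps=1, n_samples=10)
        t = _mat(g.values.copy())
        table = map_linear(g, t, p_report_threshold=1.0)
        rec = table.records.iloc[0]
        assert rec["beta"] == pytest.approx(1.0)
        assert 0 < rec["p"] <= np.finfo(float).tiny * 10

    def test_orthogonal_trait_gives_t_zero_p_one(self):
        g = GenotypeMatrix(["s1"], [f"s{j}" for j in range(4)],
                           np.array([[-1.0, 1.0, -1.0, 1.0]]))
        t = _mat([[-1.0, -1.0, 1.0, 1.0]])
        table = map_linear(g, t, p_report_threshold=1.0)
        rec = table.records.iloc[0]
        assert rec["stat"] == pytest.approx(0.0, abs=1e-12)
        assert rec["p"] == pytest.approx(1.0)

    def test_matches_per_pair_ols_with_covariates(self, rng):
        """Matrix-form t/p/beta vs explicit full-design OLS, 100x50 pairs."""
        n = 40
        G = make_genotypes(rng, n_snps=100, n_samples=n)
        T = make_expression(rng, n_genes=50, n_samples=n)
        cov = rng.standard_normal((2, n))
        covm = CovariateMatrix(["c0", "c1"], T.sample_ids, cov)
        _beta, tstat, p, _df = linear_stats(G, T, covm)
        D = np.column_stack([np.ones(n), cov.T])
        max_dt = max_dp = 0.0
        for i in range(0, 100, 7):
            for j in range(0, 50, 5):
                X = np.column_stack([D, G.values[i]])
                b, t_or, p_or = ols_fit(T.values[j], X)
                max_dt = max(max_dt, abs(tstat[i, j] - t_or[-1]))
                max_dp = max(max_dp, abs(p[i, j] - p_or[-1]))
        assert max_dt < 1e-8 and max_dp < 1e-8

    def test_block_partition_invariance(self, rng):
        G = make_genotypes(rng, n_snps=8, n_samples=30)
        T = make_expression(rng, n_genes=13, n_samples=30)
        ref = map_linear(G, T, p_report_threshold=0.5, block_size=1000)
        alt = map_linear(G, T, p_report_threshold=0.5, block_size=3)
        key = ["snp", "trait"]
        pd.testing.assert_frame_equal(
            ref.records.sort_values(key).reset_index(drop=True),
            alt.records.sort_values(key).reset_index(drop=True))

    def test_trait_scaling_leaves_t_and_p_and_scales_beta(self, rng):
        G = make_genotypes(rng, n_snps=3, n_samples=25)
        T = make_expression(rng, n_genes=2, n_samples=25)
        T2 = SampleMatrix(T.row_ids, T.sample_ids, 4.0 * T.values)
        b1, t1, p1, _ = linear_stats(G, T)
        b2, t2, p2, _ = linear_stats(G, T2)
        np.testing.assert_allclose(t1, t2, atol=1e-10)
        np.testing.assert_allclose(p1, p2, atol=1e-12)
        np.testing.assert_allclose(4.0 * b1, b2, atol=1e-10)

    def test_threshold_must_be_positive(self, rng):
        G = make_genotypes(rng, 2, 10)
        with pytest.raises(ValueError):
            map_linear(G, make_expression(rng, 2, 10), p_report_threshold=0.0)

    def test_null_calibration(self):
        """Independent Gaussian G and T: p <= alpha at the nominal rate."""
        rng = np.random.default_rng(7)
        G = make_genotypes(rng, n_snps=500, n_samples=100)
        T = make_expression(rng, n_genes=200, n_samples=100)
        _b, _t, p, _df = linear_stats(G, T)
        m = p.size  # 1e5 tests
        for alpha in (0.05, 0.001):
            frac = (p <= alpha).mean()
            half = 2.576 * np.sqrt(alpha * (1 - alpha) / m)
            assert abs(frac - alpha) < half, (alpha, frac)


class TestMapAnova:
    def test_perfect_class_separation(self):
        g = np.repeat([0.0, 1.0, 2.0], 3)
        G = GenotypeMatrix(["s1"], [f"s{j}" for j in range(9)], g[None, :])
        T = _mat(g[None, :] + 1e-9 * np.arange(9))
        table = map_anova(G, T, p_report_threshold=1.0)
        assert table.records.iloc[0]["p"] < 1e-6

    def test_constant_trait_skipped(self, rng):
        G = make_genotypes(rng, 1, 12, coded=True)
        T = _mat(np.ones((1, 12)))
        table = map_anova(G, T, p_report_threshold=1.0)
        assert table.skipped_traits == ["t0"]
        assert len(table) == 0

    def test_non_integer_genotypes_error(self, rng):
        G = make_genotypes(rng, 2, 10, coded=False)
        with pytest.raises(ValueError, match="0/1/2"):
            map_anova(G, make_expression(rng, 2, 10))

    def test_matches_two_dummy_regression_f(self, rng):
        """F and p vs explicit dummy-variable regression, 30x20 pairs."""
        n = 60
        G = make_genotypes(rng, n_snps=30, n_samples=n, coded=True)
        T = make_expression(rng, n_genes=20, n_samples=n)
        table = map_anova(G, T, p_report_threshold=1.0)
        got = table.records.set_index(["snp", "trait"])
        for i in range(0, 30, 5):
            g = G.values[i]
            classes = sorted(set(g))
            if len(classes) < 2:
                continue
            dummies = np.column_stack([(g == c).astype(float) for c in classes[1:]])
            X_full = np.column_stack([np.ones(n), dummies])
            X_red = np.ones((n, 1))
            q = len(classes) - 1
            dfden = n - 1 - q
            for j in range(0, 20, 4):
                y = T.values[j]
                rss = []
                for X in (X_red, X_full):
                    b, *_ = np.linalg.lstsq(X, y, rcond=None)
                    r = y - X @ b
                    rss.append(r @ r)
                F = ((rss[0] - rss[1]) / q) / (rss[1] / dfden)
                p = stats.f.sf(F, q, dfden)
                rec = got.loc[(G.row_ids[i], T.row_ids[j])]
                assert abs(rec["stat"] - F) < 1e-8
                assert abs(rec["p"] - p) < 1e-8


class TestFdr:
    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03], 3),
                                   [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_fdr([0.2], 1), [0.2])

    def test_matches_reference_implementation(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=1000)
        q = bh_fdr(p, 1000)
        _, q_ref, *_ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, atol=1e-12)

    def test_larger_multiplicity_scales_q(self):
        q = bh_fdr([0.001], 100)
        assert q[0] == pytest.approx(0.1)

    def test_monotone_in_sorted_p(self, rng):
        p = np.sort(rng.uniform(size=50))
        q = bh_fdr(p, 200)
        assert np.all(np.diff(q) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([1.5], 1)


class TestEmpiricalFdr:
    def test_null_data_gives_fdr_near_one(self, rng):
        G = make_genotypes(rng, n_snps=40, n_samples=60)
        T = make_expression(rng, n_genes=40, n_samples=60)
        fdr = empirical_fdr(G, T, threshold=0.05, n_perm=10, seed=0)
        assert 0.5 < fdr < 2.0

    def test_overwhelming_signal_gives_fdr_near_zero(self, rng):
        G = make_genotypes(rng, n_snps=5, n_samples=50)
        vals = rng.standard_normal((5, 50))
        vals[0] = G.values[0]  # one planted perfect association
        T = SampleMatrix([f"t{i}" for i in range(5)], G.sample_ids, vals)
        fdr = empirical_fdr(G, T, threshold=1e-10, n_perm=10, seed=0)
        assert fdr < 0.2

    def test_seeded_rerun_is_identical(self, rng):
        G = make_genotypes(rng, n_snps=10, n_samples=40)
        T = make_expression(rng, n_genes=10, n_samples=40)
        a = empirical_fdr(G, T, threshold=0.05, n_perm=5, seed=42)
        b = empirical_fdr(G, T, threshold=0.05, n_perm=5, seed=42)
        assert a == b

    def test_no_discoveries_returns_nan(self, rng):
        G = make_genotypes(rng, n_snps=2, n_samples=20)
        T = make_expression(rng, n_genes=2, n_samples=20)
        assert np.isnan(empirical_fdr(G, T, threshold=1e-300, n_perm=2, seed=0))


class TestSummaries:
    def test_qq_single_point(self):
        tab = qq_summary([0.5])
        assert tab["expected_neglog10_p"].iloc[0] == pytest.approx(-np.log10(0.5))
        assert tab["observed_neglog10_p"].iloc[0] == pytest.approx(-np.log10(0.5))

    def test_qq_uniform_grid_matches_expected(self):
        tab = qq_summary([0.125, 0.625, 0.375, 0.875])
        np.testing.assert_allclose(tab["observed_neglog10_p"],
                                   tab["expected_neglog10_p"], atol=1e-12)

    def test_manhattan_takes_min_p_per_snp(self, rng):
        from nqtl.mapping import AssociationTable
        recs = pd.DataFrame({
            "snp": ["a", "a", "b"], "trait": ["t1", "t2", "t1"],
            "beta": 0.0, "stat": 0.0, "p": [0.1, 0.001, 0.01], "fdr": 0.5,
        })
        table = AssociationTable(recs, 10, "linear", 1.0)
        best = manhattan_summary(table).set_index("snp")
        assert best.loc["a", "neglog10_p"] == pytest.approx(3.0)
        assert best.loc["b", "neglog10_p"] == pytest.approx(2.0)

    def test_manhattan_matches_groupby_oracle(self, rng):
        from nqtl.mapping import AssociationTable
        recs = pd.DataFrame({
            "snp": rng.choice(list("abcde"), 200),
            "trait": rng.choice([f"t{i}" for i in range(20)], 200),
            "beta": 0.0, "stat": 0.0, "p": rng.uniform(size=200), "fdr": 0.5,
        })
        table = AssociationTable(recs, 1000, "linear", 1.0)
        best = manhattan_summary(table).set_index("snp")["p"]
        oracle = recs.groupby("snp")["p"].min()
        for s in oracle.index:
            assert best[s] == oracle[s]


class TestMafFilter:
    def test_all_reference_row_removed(self):
        G = GenotypeMatrix(["a", "b"], list("wxyz"),
                           np.array([[0.0, 0, 0, 0], [0, 1, 2, 1]]))
        kept = maf_filter(G, maf_min=0.05)
        assert kept.row_ids == ["b"]

    def test_balanced_row_retained(self):
        G = GenotypeMatrix(["a"], list("wxyz"), np.array([[0.0, 1, 2, 1]]))
        assert maf_filter(G, maf_min=0.05).row_ids == ["a"]

    def test_matches_allele_counting_oracle(self, rng):
        G = make_genotypes(rng, n_snps=50, n_samples=30, coded=True)
        kept = set(maf_filter(G, maf_min=0.1).row_ids)
        for i, row in enumerate(G.values):
            f = row.sum() / (2 * len(row))
            assert (G.row_ids[i] in kept) == (min(f, 1 - f) >= 0.1)

    def test_default_is_off(self, rng):
        G = make_genotypes(rng, n_snps=5, n_samples=10, coded=True)
        assert maf_filter(G).row_ids == G.row_ids

    def test_real_scores_rejected(self, rng):
        with pytest.raises(ValueError):
            maf_filter(make_genotypes(rng, 2, 10, coded=False), 0.1)
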