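"""Genotype QC, HWE, ancestry PCA, association, LD, thresholds."""

import math

import numpy as np
import pandas as pd
import pytest

from poppkgx import (
    GenotypeMatrix,
    QCThresholds,
    assoc_linear,
    bonferroni_threshold,
    hwe_test,
    ld_r2,
    locus_scan,
    pca_ancestry,
    qc_filter,
)


def make_matrix(dosages: np.ndarray, imputation_r2=None, chrom="2", pos0=1000) -> GenotypeMatrix:
    n, m = dosages.shape
    ids = [f"v{j}" for j in range(m)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(pos0, pos0 + m),
            "ref": "C",
            "alt": "T",
            "imputation_r2": imputation_r2 if imputation_r2 is not None else np.ones(m),
        },
        index=ids,
    )
    dosage = pd.DataFrame(dosages, index=pd.RangeIndex(1, n + 1, name="sample_id"), columns=ids)
    return GenotypeMatrix(dosage, variants)


class TestHWE:
    def test_exact_hwe_proportions_give_p_one(self):
        """The most probable configuration sums every configuration: p = 1."""
        assert hwe_test(25, 50, 25) == pytest.approx(1.0, abs=1e-9)

    def test_monomorphic_is_p_one(self):
        assert hwe_test(100, 0, 0) == 1.0

    def test_extreme_het_deficit_below_threshold(self):
        """Total heterozygote absence at 50/50 allele split is wildly off HWE."""
        assert hwe_test(50, 0, 50) < 1e-8

    @pytest.mark.parametrize(
        "counts", [(5, 3, 2), (8, 1, 1), (2, 6, 2), (1, 1, 8), (4, 4, 0)]
    )
    def test_matches_enumeration_oracle(self, counts):
        """Brute-force enumeration over heterozygote configurations.

        Exact rational arithmetic of the conditional pmf
        P(het | n, minor-allele count) = n! / (homRef! het! homAlt!)
        * 2^het * n_a! (2n-n_a)! / (2n)!.
        """
        from fractions import Fraction

        n_AA, n_Aa, n_aa = counts
        n = n_AA + n_Aa + n_aa
        n_a = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
        f = math.factorial

        def prob(het):
            hom_a = (n_a - het) // 2
            hom_A = n - het - hom_a
            return (
                Fraction(f(n), f(hom_A) * f(het) * f(hom_a))
                * Fraction(2**het)
                * Fraction(f(n_a) * f(2 * n - n_a), f(2 * n))
            )

        probs = {h: prob(h) for h in range(n_a % 2, n_a + 1, 2)}
        p_obs = probs[n_Aa]
        expected = float(sum(p for p in probs.values() if p <= p_obs))
        assert hwe_test(*counts) == pytest.approx(min(expected, 1.0), rel=1e-9)

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 0, 5)
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


class TestQC:
    def test_constructed_failure_counts(self):
        """10 variants: 3 fail MAF, 1 fails call rate, 6 survive."""
        rng = np.random.default_rng(0)
        n = 200
        cols = []
        # 6 clean common variants
        for maf in (0.2, 0.3, 0.4, 0.25, 0.35, 0.45):
            cols.append(rng.binomial(2, maf, n).astype(float))
        # 3 below the MAF threshold
        for maf in (0.0, 0.01, 0.02):
            cols.append(rng.binomial(2, maf, n).astype(float))
        # 1 with 10% missingness (call rate 0.90 < 0.95)
        bad = rng.binomial(2, 0.3, n).astype(float)
        bad[: n // 10] = np.nan
        cols.append(bad)
        g = make_matrix(np.column_stack(cols))
        filtered, report = qc_filter(g)
        assert filtered.n_variants == 6
        assert report.loc["maf", "any_failing"] == 3
        assert report.loc["call_rate", "any_failing"] == 1
        assert report.loc["total_excluded", "any_failing"] == 4

    def test_all_passing_is_identity(self):
        rng = np.random.default_rng(1)
        g = make_matrix(rng.binomial(2, 0.3, (100, 5)).astype(float))
        filtered, report = qc_filter(g)
        assert filtered.n_variants == 5
        assert report.loc["total_excluded", "any_failing"] == 0

    def test_maf_exactly_at_threshold_retained(self):
        """Strict '< 0.05' exclusion keeps a MAF = 0.05 variant."""
        n = 100
        d = np.zeros(n)
        d[:10] = 1.0  # 10 copies / 200 alleles = MAF 0.05 exactly
        g = make_matrix(d[:, None])
        filtered, _ = qc_filter(g)
        assert filtered.n_variants == 1

    def test_low_imputation_excluded(self):
        rng = np.random.default_rng(2)
        g = make_matrix(
            rng.binomial(2, 0.3, (50, 2)).astype(float), imputation_r2=[0.2, 0.9]
        )
        filtered, report = qc_filter(g)
        assert list(filtered.dosage.columns) == ["v1"]
        assert report.loc["imputation_r2", "any_failing"] == 1

    def test_empty_matrix_is_empty_result(self):
        g = make_matrix(np.zeros((5, 0)))
        filtered, report = qc_filter(g)
        assert filtered.n_variants == 0


class TestPCA:
    def test_two_populations_separate_on_pc1(self):
        """Divergent allele frequencies put the populations at opposite ends."""
        rng = np.random.default_rng(3)
        n1, n2, m = 80, 80, 150
        f1 = rng.uniform(0.05, 0.5, m)
        f2 = np.clip(f1 + rng.choice([-1, 1], m) * 0.3, 0.02, 0.98)
        d = np.vstack(
            [rng.binomial(2, f1, (n1, m)), rng.binomial(2, f2, (n2, m))]
        ).astype(float)
        scores = pca_ancestry(make_matrix(d), k=2)
        label = np.r_[np.zeros(n1), np.ones(n2)]
        r = np.corrcoef(scores["PC1"], label)[0, 1]
        assert abs(r) > 0.9

    def test_identical_rows_give_zero_scores(self):
        d = np.tile(np.array([0.0, 1.0, 2.0, 1.0, 0.0]), (20, 1))
        scores = pca_ancestry(make_matrix(d), k=2)
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_matches_dense_eigendecomposition(self):
        """Scores equal eigenvectors of the normalized covariance, up to sign."""
        rng = np.random.default_rng(4)
        d = rng.binomial(2, rng.uniform(0.1, 0.5, 30), (40, 30)).astype(float)
        g = make_matrix(d)
        scores = pca_ancestry(g, k=3).to_numpy()
        x = d.copy()
        mu = x.mean(axis=0)
        p = mu / 2
        sd = np.sqrt(2 * p * (1 - p))
        keep = (sd > 0) & (x.std(axis=0) > 0)
        z = (x[:, keep] - mu[keep]) / sd[keep]
        w, v = np.linalg.eigh(z @ z.T)
        order = np.argsort(w)[::-1][:3]
        ref = v[:, order] * np.sqrt(w[order])
        for j in range(3):
            assert min(
                np.abs(scores[:, j] - ref[:, j]).max(),
                np.abs(scores[:, j] + ref[:, j]).max(),
            ) < 1e-8

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.3, (50, 40)).astype(float)
        s = pca_ancestry(make_matrix(d), k=3).to_numpy()
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()


class TestAssocLinear:
    def test_closed_form_slope(self):
        """y=(1,2,4) on x=(0,1,2): OLS slope = 1.5 by hand."""
        y = pd.Series([1.0, 2.0, 4.0], index=[1, 2, 3])
        x = pd.Series([0.0, 1.0, 2.0], index=[1, 2, 3])
        res = assoc_linear(y, x)
        assert res.beta == pytest.approx(1.5, abs=1e-12)

    def test_matches_textbook_ols_with_covariates(self):
        rng = np.random.default_rng(6)
        n = 60
        x = rng.binomial(2, 0.4, n).astype(float)
        c1 = rng.standard_normal(n)
        y = 0.3 * x + 0.5 * c1 + rng.standard_normal(n)
        idx = pd.RangeIndex(n)
        res = assoc_linear(
            pd.Series(y, idx), pd.Series(x, idx), pd.DataFrame({"c1": c1}, idx)
        )
        X = np.column_stack([np.ones(n), x, c1])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 3)
        se = math.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.beta == pytest.approx(beta[1], abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)

    def test_constant_phenotype_gives_zero_beta(self):
        idx = pd.RangeIndex(30)
        y = pd.Series(np.ones(30), idx)
        x = pd.Series(np.random.default_rng(7).binomial(2, 0.4, 30).astype(float), idx)
        res = assoc_linear(y, x)
        assert res.beta == pytest.approx(0.0, abs=1e-12)

    def test_collinear_conditioning_snp_flagged(self):
        rng = np.random.default_rng(8)
        n = 50
        x = rng.binomial(2, 0.4, n).astype(float)
        idx = pd.RangeIndex(n)
        y = pd.Series(rng.standard_normal(n), idx)
        res = assoc_linear(y, pd.Series(x, idx), pd.DataFrame({"cond": x + 1e-12}, idx))
        assert not res.stable

    def test_insufficient_cases_rejected(self):
        idx = pd.RangeIndex(3)
        with pytest.raises(ValueError):
            assoc_linear(
                pd.Series([1.0, 2, 3], idx), pd.Series([0.0, 1, 2], idx),
                pd.DataFrame({"c": [1.0, 2, 3]}, idx),
            )


class TestLD:
    def test_identical_vectors_r2_one(self):
        x = np.array([0, 1, 2, 1, 0, 2.0])
        assert ld_r2(x, x) == pytest.approx(1.0)

    def test_matches_pearson(self):
        x = np.array([0, 1, 2, 1, 0, 2, 1.0])
        y = np.array([0, 0, 2, 1, 1, 2, 0.0])
        assert ld_r2(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, rel=1e-12)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(9)
        x = rng.binomial(2, 0.3, 20000).astype(float)
        y = rng.binomial(2, 0.3, 20000).astype(float)
        assert ld_r2(x, y) < 0.001

    def test_zero_variance_is_nan(self):
        assert math.isnan(ld_r2(np.ones(10), np.arange(10.0)))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            ld_r2(np.array([1.0, np.nan]), np.array([np.nan, 1.0]))


class TestBonferroni:
    @pytest.mark.parametrize("m,expected", [(9, 5.6e-3), (853, 5.9e-5), (1, 0.05)])
    def test_published_thresholds(self, m, expected):
        assert bonferroni_threshold(m) == pytest.approx(expected, rel=1e-9)

    def test_rejects_zero_tests(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestFolding:
    def test_maf_invariant_under_allele_swap(self):
        rng = np.random.default_rng(10)
        d = rng.binomial(2, 0.7, (100, 4)).astype(float)
        g1 = make_matrix(d)
        g2 = make_matrix(2.0 - d)
        np.testing.assert_allclose(
            g1.variants["maf"].to_numpy(), g2.variants["maf"].to_numpy(), atol=1e-12
        )


class TestLocusScan:
    def _cohort(self, seed=11, n=250):
        rng = np.random.default_rng(seed)
        causal = rng.binomial(2, 0.41, n).astype(float)
        noise = rng.binomial(2, 0.3, (n, 3)).astype(float)
        d = np.column_stack([causal, noise])
        g = make_matrix(d, pos0=5000)
        y = pd.Series(
            0.12 * causal + rng.normal(0, 0.25, n),
            index=g.samples,
        )
        return g, y

    def test_zero_flank_single_variant(self):
        g, y = self._cohort()
        out = locus_scan(g, y, "2", 5000, 0, "v0")
        assert len(out) == 1
        assert out.loc[0, "variant"] == "v0"
        assert out.loc[0, "r2_to_reference"] == pytest.approx(1.0)

    def test_empty_region_empty_table(self):
        g, y = self._cohort()
        out = locus_scan(g, y, "7", 5000, 100, "v0")
        assert len(out) == 0

    def test_causal_variant_ranks_first(self):
        g, y = self._cohort()
        out = locus_scan(g, y, "2", 5001, 100, "v0")
        assert out.loc[0, "variant"] == "v0"

    def test_conditioning_on_causal_removes_signal(self):
        g, y = self._cohort()
        cond = locus_scan(g, y, "2", 5001, 100, "v0", condition_on="v0")
        assert "v0" not in set(cond["variant"])
        assert cond["p"].min() > 1e-3


class TestVCFRoundtrip:
    def test_to_vcf_from_vcf_preserves_dosages(self, tmp_path):
        rng = np.random.default_rng(12)
        d = rng.binomial(2, 0.4, (30, 5)).astype(float)
        d[3, 2] = np.nan
        g = make_matrix(d)
        path = tmp_path / "test.vcf"
        g.to_vcf(path)
        g2 = GenotypeMatrix.from_vcf(path)
        assert set(g2.dosage.columns) == set(g.dosage.columns)
        for v in g.dosage.columns:
            np.testing.assert_allclose(
                g2.dosage[v].to_numpy(float), g.dosage[v].to_numpy(float),
                equal_nan=True,
            )
        np.testing.assert_array_equal(
            g2.variants.loc[g.dosage.columns, "pos"], g.variants["pos"]
        )
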