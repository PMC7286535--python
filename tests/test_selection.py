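"""Selection scan: projections, calibration, clustering, region tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genopca.empca import GenotypePCA
from genopca.exceptions import AlignmentError, DegenerateScanError
from genopca.genotypes import compute_standardization, standardized_matrix
from genopca.selection import (
    SelectionScan,
    cluster_loci,
    combined_statistic,
    genomic_inflation,
    region_freq_test,
    residual_projections,
    selection_statistics,
    significance_threshold,
)
from genopca.simulate import SimulationSpec, simulate_genotypes

from conftest import random_genotypes


class TestResidualProjections:
    def _orthogonal_scores(self, rng, k, n):
        return np.linalg.qr(rng.standard_normal((n, k)))[0].T

    def test_full_projection_zeroes_in_span_snps(self, rng):
        """Under the literal all-directions residual, a SNP inside the score
        span has zero projection on every PC (the formula's degeneracy)."""
        geno = random_genotypes(rng, 30, 40)
        params = compute_standardization(geno)
        scores = self._orthogonal_scores(rng, 3, 40)
        d = residual_projections(geno, params, scores, projection="full")
        np.testing.assert_allclose(d, 0.0, atol=1e-10)

    def test_orthogonal_snp_zero_under_both_conventions(self):
        rng = np.random.default_rng(2)
        n = 24
        scores = self._orthogonal_scores(rng, 2, n)
        # build a genotype row, then scores orthogonal to its standardized form
        geno = random_genotypes(rng, 5, n)
        params = compute_standardization(geno)
        y = standardized_matrix(geno, params)
        # orthogonalize the score rows against row 0 of y
        y0 = y[0] / np.linalg.norm(y[0])
        scores = scores - (scores @ y0)[:, None] * y0[None, :]
        sub = geno.take_snps(np.array([0]))
        sub_params = compute_standardization(sub)
        for mode in ("loo", "full"):
            d = residual_projections(sub, sub_params, scores, projection=mode)
            np.testing.assert_allclose(d[0], 0.0, atol=1e-10)

    def test_loo_matches_dense_oracle(self, rng):
        """4-sample, 2-PC worked instance against an explicit projection oracle."""
        geno = random_genotypes(rng, 6, 4)
        params = compute_standardization(geno)
        scores = rng.standard_normal((2, 4))  # deliberately non-orthogonal
        d = residual_projections(geno, params, scores)
        y = standardized_matrix(geno, params)
        xhat = scores / np.linalg.norm(scores, axis=1)[:, None]
        for k in range(2):
            others = xhat[[1 - k]]
            proj = others.T @ np.linalg.solve(others @ others.T, others)
            resid = y - y @ proj
            np.testing.assert_allclose(d[:, k], resid @ xhat[k], atol=1e-12)

    def test_loo_equals_plain_projection_for_orthogonal_scores(self, rng):
        geno = random_genotypes(rng, 20, 30)
        params = compute_standardization(geno)
        scores = self._orthogonal_scores(rng, 4, 30) * np.array([[5.0], [4.0], [3.0], [2.0]])
        d = residual_projections(geno, params, scores)
        y = standardized_matrix(geno, params)
        xhat = scores / np.linalg.norm(scores, axis=1)[:, None]
        np.testing.assert_allclose(d, y @ xhat.T, atol=1e-10)

    def test_sample_mismatch_raises(self, rng):
        geno = random_genotypes(rng, 5, 10)
        with pytest.raises(AlignmentError):
            residual_projections(
                geno, compute_standardization(geno), np.zeros((2, 11))
            )


class TestStatistics:
    def test_constant_column_degenerate(self):
        d = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        with pytest.raises(DegenerateScanError):
            selection_statistics(d)

    def test_null_calibration_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.0, 2.5, size=(100_000, 1))
        sigma2, s1, p1 = selection_statistics(d)
        assert sigma2[0] == pytest.approx(6.25, rel=0.05)
        assert s1.mean() == pytest.approx(1.0, abs=0.02)
        assert (p1 < 0.05).mean() == pytest.approx(0.05, abs=0.005)
        _, s2, _ = selection_statistics(2.0 * d)
        np.testing.assert_allclose(s1, s2, rtol=1e-12)

    def test_combined_reduces_and_sums(self):
        rng = np.random.default_rng(1)
        d = rng.standard_normal((500, 1))
        _, s, p = selection_statistics(d)
        comb, comb_p = combined_statistic(s)
        np.testing.assert_allclose(comb, s[:, 0])
        np.testing.assert_allclose(comb_p, p[:, 0])
        d5 = rng.standard_normal((500, 5))
        _, s5, _ = selection_statistics(d5)
        comb5, _ = combined_statistic(s5)
        np.testing.assert_allclose(comb5, s5.sum(axis=1))

    def test_combined_null_point(self):
        comb, p = combined_statistic(np.zeros((3, 4)))
        assert (p == 1.0).all()

    def test_combined_null_matches_chi2_quantiles(self):
        rng = np.random.default_rng(2)
        d = rng.standard_normal((100_000, 5)) * np.array([3.0, 2.0, 1.5, 1.0, 0.5])
        _, s, _ = selection_statistics(d)
        comb, _ = combined_statistic(s)
        lam = genomic_inflation(comb, df=5)
        assert lam == pytest.approx(1.0, abs=0.02)
        qs = np.linspace(0.05, 0.95, 19)
        emp = np.quantile(comb, qs)
        theo = stats.chi2.ppf(qs, df=5)
        assert np.abs(emp / theo - 1.0).max() < 0.03


class TestInflation:
    def test_chi2_sample_near_one(self):
        draws = stats.chi2.rvs(1, size=100_000, random_state=3)
        assert genomic_inflation(draws) == pytest.approx(1.0, abs=0.02)

    def test_scale_equivariance(self):
        draws = stats.chi2.rvs(1, size=10_000, random_state=4)
        assert genomic_inflation(2 * draws) == pytest.approx(
            2 * genomic_inflation(draws), rel=1e-12
        )

    def test_single_median_statistic(self):
        med = stats.chi2.ppf(0.5, 1)
        assert genomic_inflation(np.array([med])) == pytest.approx(1.0, abs=1e-12)


class TestThreshold:
    def test_paper_scale_arithmetic(self):
        thr = significance_threshold(516_140, 6, 0.05)
        assert thr == pytest.approx(0.05 / (6 * 516_140), rel=1e-15)
        assert thr == pytest.approx(1.615e-8, rel=1e-3)

    def test_no_correction_base_case(self):
        assert significance_threshold(1, 1, 0.05) == 0.05

    def test_monotone_in_snp_count(self):
        ts = [significance_threshold(n, 6, 0.05) for n in (10, 100, 1000)]
        assert ts[0] > ts[1] > ts[2]


class TestClusterLoci:
    def test_window_arithmetic(self):
        hits = pd.DataFrame(
            {
                "chrom": ["1"] * 3,
                "id": ["a", "b", "c"],
                "pos": [1_000_000, 1_300_000, 5_000_000],
                "p": [1e-12, 1e-9, 1e-10],
            }
        )
        loci = cluster_loci(hits)
        assert loci["lead_id"].tolist() == ["a", "c"]
        assert loci.loc[0, "n_members"] == 2
        assert loci.loc[0, "window_start"] == 500_000
        assert loci.loc[0, "window_end"] == 1_500_000

    def test_single_hit(self):
        hits = pd.DataFrame({"chrom": ["2"], "id": ["x"], "pos": [42], "p": [1e-9]})
        loci = cluster_loci(hits)
        assert len(loci) == 1 and loci.loc[0, "lead_id"] == "x"

    def test_tie_broken_by_position(self):
        hits = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "id": ["far", "near"],
                "pos": [9_000_000, 1_000_000],
                "p": [1e-10, 1e-10],
            }
        )
        loci = cluster_loci(hits)
        assert loci.loc[0, "lead_id"] == "near"

    def test_chromosomes_not_merged(self):
        hits = pd.DataFrame(
            {
                "chrom": ["1", "2"],
                "id": ["a", "b"],
                "pos": [100, 100],
                "p": [1e-12, 1e-11],
            }
        )
        assert len(cluster_loci(hits)) == 2


class TestRegionFreqTest:
    def test_equal_frequencies_null(self):
        g = np.array([1] * 50 + [1] * 50)
        labels = np.array(["a"] * 50 + ["b"] * 50)
        out = region_freq_test(g, labels)
        assert np.allclose(out["z"], 0.0)
        assert np.allclose(out["p"], 1.0)

    def test_hand_formula(self):
        """Region freq 0.6 on 1000 alleles vs rest 0.5 on 10000 alleles."""
        g = np.concatenate([
            np.repeat([2, 1], [100, 400]),     # 500 samples, 600/1000 alt
            np.repeat([2, 1, 0], [500, 4000, 500]),  # 5000 samples, 5000/10000
        ])
        labels = np.array(["r"] * 500 + ["o"] * 5000)
        out = region_freq_test(g, labels).set_index("region")
        p1, n1, p2, n2 = 0.6, 1000, 0.5, 10000
        pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
        z_hand = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        assert out.loc["r", "z"] == pytest.approx(z_hand, abs=1e-12)
        assert out.loc["r", "p"] == pytest.approx(2 * stats.norm.sf(abs(z_hand)), abs=1e-15)

    def test_allele_swap_flips_sign(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, 300)
        labels = np.repeat(["a", "b", "c"], 100)
        out1 = region_freq_test(g, labels)
        out2 = region_freq_test(2 - g, labels)
        np.testing.assert_allclose(out1["z"], -out2["z"], atol=1e-12)
        np.testing.assert_allclose(out1["p"], out2["p"], atol=1e-12)

    def test_bonferroni_and_empty_region(self):
        g = np.array([0, 1, 2, 1])
        labels = np.array(["a", "a", "b", "b"])
        out = region_freq_test(g, labels, bonferroni_factor=100)
        assert (out["p_bonferroni"] <= 1.0).all()
        g3 = np.array([0, 1, 2, 1, 0, 2])
        labels3 = np.array(["a", "a", "b", "b", "c", "c"])
        missing = np.array([True, True, False, False, False, False])
        with pytest.warns(UserWarning, match="no called alleles"):
            out = region_freq_test(g3, labels3, missing_mask=missing)
        assert out["region"].tolist() == ["b", "c"]


class TestScanEndToEnd:
    def test_null_scan_roughly_calibrated(self):
        """PCs fitted on the panel itself: per-PC stats chi^2_1-like in bulk."""
        spec = SimulationSpec(m=8000, n=800, q=3, fst=0.02, seed=11)
        geno, labels, _ = simulate_genotypes(spec)
        from genopca.genotypes import drop_monomorphic

        geno, _ = drop_monomorphic(geno)
        res = GenotypePCA(geno, k=2).fit(seed=0)
        scan = SelectionScan(res, geno, params=res.model.params)
        out = scan.fit()
        lam = out.genomic_inflation()
        for i in range(2):
            assert 0.85 < lam[f"PC{i + 1}"] < 1.15
        table = out.table()
        assert (table["stat_combined"] >= 0).all()
        np.testing.assert_allclose(
            table["stat_combined"],
            table[["stat_pc1", "stat_pc2"]].sum(axis=1),
            rtol=1e-12,
        )
        assert ((table["p_combined"] > 0) & (table["p_combined"] <= 1)).all()

    def test_planted_differentiation_detected(self):
        """SNPs with 5x amplified inter-population shifts dominate the scan
        while the neutral background stays calibrated."""
        rng = np.random.default_rng(21)
        m, n, q, fst = 6000, 1200, 6, 0.05
        spec = SimulationSpec(m=m, n=n, q=q, fst=fst, seed=21)
        geno, labels, freqs = simulate_genotypes(spec)
        f0 = freqs.mean(axis=1)
        planted = rng.choice(m, 50, replace=False)
        amp = np.clip(f0[planted, None] + 5.0 * (freqs[planted] - f0[planted, None]), 0, 1)
        values = geno.values.copy()
        for row, j in enumerate(planted):
            for pop in range(q):
                cols = np.flatnonzero(labels == pop)
                values[j, cols] = rng.binomial(2, amp[row, pop], cols.size)
        from genopca.genotypes import GenotypeMatrix, drop_monomorphic

        geno2, _ = drop_monomorphic(GenotypeMatrix(values))
        res = GenotypePCA(geno2, k=q - 1).fit(seed=0)
        out = SelectionScan(res, geno2, params=res.model.params).fit()
        comb = out.combined_statistics
        planted_med = np.median(comb[planted])
        assert planted_med > stats.chi2.ppf(1 - 1e-6, df=q - 1)
        neutral = np.ones(geno2.m, dtype=bool)
        neutral[planted] = False
        lam_neutral = genomic_inflation(
            out.per_pc_statistics[neutral].ravel(), df=1
        )
        assert 0.8 < lam_neutral < 1.2
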