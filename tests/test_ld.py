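import numpy as np
import pytest

import cnvmqtl as cm
from cnvmqtl.ld import _snp_gap, conditional_scan
from cnvmqtl.types import GenomicInterval
from conftest import pearson_r2_bruteforce


class TestLdR2:
    def test_identical_vectors(self):
        assert cm.ld_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cm.ld_r2([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # cov terms by hand: r^2 = 2.56/3.36 = 16/21
        assert cm.ld_r2([0, 1, 2, 1, 0], [0, 1, 1, 1, 0]) == pytest.approx(16 / 21, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            cm.ld_r2([1, 1, 1, 1], [0, 1, 0, 1])

    def test_matches_summation_oracle_on_random_vectors(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 60))
            a = rng.integers(0, 4, n).astype(float)
            b = (a + rng.integers(0, 3, n)).astype(float)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            assert cm.ld_r2(a, b) == pytest.approx(
                pearson_r2_bruteforce(list(a), list(b)), abs=1e-12
            )

    def test_pairwise_complete_filtering(self):
        a = [0, 1, 2, np.nan, 1, 0]
        b = [0, 1, 2, 5, 1, np.nan]
        assert cm.ld_r2(a, b) == pytest.approx(1.0)


class TestBestTagSnp:
    def _snps(self, rows, positions, chrom="chr1"):
        ivs = [GenomicInterval(chrom, p, p + 1, f"s{i}") for i, p in enumerate(positions)]
        return cm.GenotypeMatrix(ivs, [f"x{j}" for j in range(len(rows[0]))], np.array(rows, float))

    def test_argmax_r2_selected(self, rng):
        cnv = GenomicInterval("chr1", 100_000, 150_000, "cnv")
        g = rng.integers(0, 3, 30).astype(float)
        noisy = np.where(rng.random(30) < 0.4, rng.integers(0, 3, 30), g)
        snps = self._snps([rng.integers(0, 3, 30), g, noisy], [200_000, 300_000, 400_000])
        rec = cm.best_tag_snp(cnv, snps, g)
        assert rec.snp_id == "s1" and rec.r2 == pytest.approx(1.0)

    def test_none_outside_window(self, rng):
        cnv = GenomicInterval("chr1", 0, 1_000, "cnv")
        g = rng.integers(0, 3, 20).astype(float)
        snps = self._snps([g], [5_000_000])
        assert cm.best_tag_snp(cnv, snps, g, window=1_000_000) is None

    def test_tie_breaks_to_lower_coordinate(self, rng):
        cnv = GenomicInterval("chr1", 100_000, 150_000, "cnv")
        g = rng.integers(0, 3, 20).astype(float)
        snps = self._snps([g, g], [400_000, 200_000])
        rec = cm.best_tag_snp(cnv, snps, g)
        assert rec.snp_id == "s1"  # position 200,000

    def test_gap_measured_from_interval_ends(self):
        cnv = GenomicInterval("chr1", 1_000, 2_000, "cnv")
        assert _snp_gap(cnv, GenomicInterval("chr1", 1_500, 1_501)) == 0
        assert _snp_gap(cnv, GenomicInterval("chr1", 2_500, 2_501)) == 501
        assert _snp_gap(cnv, GenomicInterval("chr1", 400, 401)) == 600


class TestConditionalAssociation:
    def test_perfect_tag_is_non_identifiable(self, rng):
        g = rng.binomial(2, 0.4, 50).astype(float)
        y = 0.1 * g + rng.normal(0, 0.01, 50)
        res = cm.conditional_association(y, g, [g.copy()])
        assert not res.identifiable and not res.independent

    def test_zero_covariates_matches_marginal_ols(self, rng):
        import statsmodels.api as sm
        from scipy import stats

        g = rng.binomial(2, 0.4, 60).astype(float)
        y = 0.3 * g + rng.normal(0, 1, 60)
        res = cm.conditional_association(y, g, [])
        marg = sm.OLS(stats.rankdata(y), sm.add_constant(g)).fit()
        assert res.conditional_p == pytest.approx(marg.pvalues[1], abs=1e-9)

    def test_planted_effect_survives_independent_covariate(self, rng):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            g = r.binomial(2, 0.3, 200).astype(float)
            snp = r.binomial(2, 0.3, 200).astype(float)
            z = (g - g.mean()) / g.std()
            y = 1 / (1 + np.exp(-(0.7 * z + r.normal(0, 1, 200))))
            hits += cm.conditional_association(y, g, [snp]).independent
        assert hits >= 36  # >=90% power bound, pre-confirmed by pilot

    def test_null_cnv_with_driving_snp_keeps_nominal_size(self):
        calls = 0
        for seed in range(100):
            r = np.random.default_rng(1000 + seed)
            g = r.binomial(2, 0.3, 200).astype(float)
            snp = r.binomial(2, 0.3, 200).astype(float)
            zs = (snp - snp.mean()) / snp.std()
            y = 1 / (1 + np.exp(-(0.7 * zs + r.normal(0, 1, 200))))
            calls += cm.conditional_association(y, g, [snp]).independent
        # nominal 5% rate, 3 binomial SD slack
        assert calls <= 100 * 0.05 + 3 * np.sqrt(100 * 0.05 * 0.95)

    def test_noise_covariate_barely_moves_p(self):
        deltas = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            g = r.binomial(2, 0.3, 1000).astype(float)
            y = 0.1 * g + r.normal(0, 1, 1000)
            noise_cov = r.normal(0, 1, 1000)
            p0 = cm.conditional_association(y, g, []).conditional_p
            p1 = cm.conditional_association(y, g, [noise_cov]).conditional_p
            deltas.append(abs(p1 - p0))
        assert np.median(deltas) < 0.05

    def test_conditional_scan_selects_nearby_covariates(self, small_dataset):
        d = small_dataset
        scheme = cm.PermutationScheme(n_perm=100, seed=6)
        records = cm.call_significant(
            cm.run_scan(d["cnvs"], d["meth"], cm.ScanConfig(scheme=scheme)), 0.05
        )
        results = conditional_scan(d["meth"], d["cnvs"], d["snps"], records, max_covariates=3)
        assert len(results) == len(records)
        for res in results:
            assert len(res.covariate_snp_ids) <= 3
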