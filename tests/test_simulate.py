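import numpy as np
import pytest
from scipy import stats

import cnvmqtl as cm
from cnvmqtl.ld import ld_r2


class TestCnvGenotypes:
    def test_seeded_determinism(self, small_cfg):
        a = cm.simulate_cnv_genotypes(small_cfg)
        b = cm.simulate_cnv_genotypes(small_cfg)
        assert np.array_equal(a.values, b.values)
        assert [iv.id for iv in a.variants] == [iv.id for iv in b.variants]

    def test_states_are_copy_numbers_and_polymorphic(self, small_dataset):
        vals = small_dataset["cnvs"].values
        assert vals.min() >= 0 and vals.max() <= 4
        for row in vals:
            assert len(np.unique(row)) > 1

    def test_high_maf_range_concentrates(self):
        cfg = cm.SimConfig(seed=3, n_samples=1000, n_cnvs=30, maf_range=(0.4, 0.5))
        maf = cm.simulate_cnv_genotypes(cfg).maf()
        assert np.all(maf >= 0.3)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cm.simulate_cnv_genotypes(cm.SimConfig(seed=1, n_samples=2))


class TestSnpsInLd:
    def test_target_r2_one_is_exact(self, small_dataset):
        d = small_dataset
        lp = next(p for p in d["truth"].ld_pairs if p.r2 == 1.0)
        r2 = ld_r2(d["cnvs"].row(lp.cnv_id), d["snps"].row(lp.snp_id))
        assert r2 == pytest.approx(1.0)

    def test_realized_r2_tracks_target(self):
        cfg = cm.SimConfig(seed=17, n_samples=200, n_cnvs=20, n_snps=20)
        cnvs = cm.simulate_cnv_genotypes(cfg)
        truth = cm.make_truth(cnvs, cfg, n_ld_pairs=8)
        snps = cm.simulate_snps_in_ld(cnvs, truth, cfg)
        for lp in truth.ld_pairs:
            realized = ld_r2(cnvs.row(lp.cnv_id), snps.row(lp.snp_id))
            assert realized == pytest.approx(lp.r2, abs=0.1)

    def test_independent_snps_near_zero_r2_at_large_n(self):
        cfg = cm.SimConfig(seed=19, n_samples=1000, n_cnvs=5, n_snps=10)
        cnvs = cm.simulate_cnv_genotypes(cfg)
        truth = cm.make_truth(cnvs, cfg, n_ld_pairs=0)
        snps = cm.simulate_snps_in_ld(cnvs, truth, cfg)
        r2s = [ld_r2(cnvs.values[0], row) for row in snps.values]
        assert np.median(r2s) < 0.05

    def test_paired_snp_within_1mb(self, small_dataset):
        d = small_dataset
        for lp in d["truth"].ld_pairs:
            cnv, snp = d["cnvs"].interval(lp.cnv_id), d["snps"].interval(lp.snp_id)
            assert cnv.chrom == snp.chrom
            assert abs(snp.start - cnv.midpoint) <= 1_000_000


class TestMethylation:
    def test_betas_in_unit_interval(self, small_dataset):
        beta = small_dataset["meth"].beta
        assert beta.min() > 0 and beta.max() < 1

    def test_zero_noise_gives_monotone_association(self):
        cfg = cm.SimConfig(seed=23, n_samples=40, n_cnvs=10, n_cpgs=10, noise_scale=0.0)
        cnvs = cm.simulate_cnv_genotypes(cfg)
        truth = cm.make_truth(cnvs, cfg, n_planted=5)
        meth = cm.simulate_methylation(cnvs, truth, cfg)
        for p in truth.planted_pairs:
            rho = stats.spearmanr(cnvs.row(p.variant_id), meth.row(p.phenotype_id)).statistic
            assert p.sign * rho > 0.9

    def test_realized_rho_tracks_target_across_seeds(self):
        # generator contract: mean |rho| within 0.15 of target over 20 seeds
        for target in (0.3, 0.5):
            realized = []
            for seed in range(20):
                cfg = cm.SimConfig(seed=300 + seed, n_samples=77, n_cnvs=10, n_cpgs=10)
                cnvs = cm.simulate_cnv_genotypes(cfg)
                truth = cm.make_truth(cnvs, cfg, n_planted=4, rho_grid=(target,))
                meth = cm.simulate_methylation(cnvs, truth, cfg)
                for p in truth.planted_pairs:
                    rho = stats.spearmanr(
                        cnvs.row(p.variant_id), meth.row(p.phenotype_id)
                    ).statistic
                    realized.append(abs(rho))
            assert np.mean(realized) == pytest.approx(target, abs=0.15)

    def test_placement_respects_mode(self, small_dataset):
        d = small_dataset
        for p in d["truth"].planted_pairs:
            mode = cm.classify_pairing(
                d["cnvs"].interval(p.variant_id), d["meth"].interval(p.phenotype_id)
            )
            assert mode == p.mode

    def test_null_sites_uncorrelated(self, small_dataset):
        d = small_dataset
        rhos = [
            abs(stats.spearmanr(d["cnvs"].values[0], d["meth"].row(cid)).statistic)
            for cid in d["truth"].null_cpg_ids[:20]
        ]
        # null |rho| at n=40 rarely exceeds ~0.43 (p≈0.005); allow one excursion
        assert sum(r > 0.45 for r in rhos) <= 1


class TestExpression:
    def test_zero_noise_negative_sign_gives_rho_minus_one(self):
        cfg = cm.SimConfig(seed=29, n_samples=30, n_cnvs=10, n_cpgs=10, n_genes=6, noise_scale=0.0)
        cnvs = cm.simulate_cnv_genotypes(cfg)
        truth = cm.make_truth(cnvs, cfg, n_planted=4, n_meth_driven_genes=4, n_cnv_driven_genes=0)
        meth = cm.simulate_methylation(cnvs, truth, cfg)
        expr = cm.simulate_expression(meth, cnvs, truth, cfg)
        neg = next(e for e in truth.expression_effects if e.sign == -1)
        rho = stats.spearmanr(meth.row(neg.mediator_id), expr.row(neg.gene_id)).statistic
        assert rho == pytest.approx(-1.0)

    def test_values_non_negative_and_deterministic(self, small_dataset):
        d = small_dataset
        assert d["expr"].values.min() >= 0
        again = cm.simulate_expression(d["meth"], d["cnvs"], d["truth"], d["cfg"])
        assert np.array_equal(d["expr"].values, again.values)

    def test_unknown_mediator_rejected(self, small_dataset):
        d = small_dataset
        bad = cm.SyntheticTruth(
            expression_effects=[cm.ExpressionEffect("g", "nope", "cpg", 1)]
        )
        with pytest.raises(KeyError):
            cm.simulate_expression(d["meth"], d["cnvs"], bad, d["cfg"])


class TestFeatureTrack:
    def test_uniform_matches_genome_fraction(self, small_dataset):
        d = small_dataset
        roi = list(d["cnvs"].variants)
        cfg = d["cfg"]
        track = cm.simulate_feature_track(roi, 1.0, cfg, n_features=10_000)
        from cnvmqtl._util import MergedTrackIndex

        idx = MergedTrackIndex(roi)
        mids = np.array([iv.midpoint for iv in track.intervals])
        chroms = np.array([iv.chrom for iv in track.intervals])
        inside = idx.overlaps(chroms, mids, mids + 1).mean()
        from cnvmqtl._util import merge_intervals

        frac = sum(iv.length for iv in merge_intervals(roi)) / sum(cfg.chrom_lengths.values())
        sd = np.sqrt(frac * (1 - frac) / 10_000)
        assert abs(inside - frac) < 3 * sd + 1e-3

    def test_bias_increases_inside_fraction(self, small_dataset):
        d = small_dataset
        roi = list(d["cnvs"].variants)

        def inside_frac(bias):
            track = cm.simulate_feature_track(roi, bias, d["cfg"], n_features=2000)
            return np.mean([any(iv.overlaps(r) for r in roi) for iv in track.intervals])

        assert inside_frac(10.0) > inside_frac(1.0)

    def test_features_within_bounds(self, small_dataset):
        d = small_dataset
        track = cm.simulate_feature_track(list(d["cnvs"].variants), 1.0, d["cfg"], n_features=500)
        for iv in track.intervals:
            assert 0 <= iv.start < iv.end <= d["cfg"].chrom_lengths[iv.chrom]


class TestHiCSim:
    def _planted(self, cfg):
        a = cm.GenomicInterval("chr1", 1_000_000, 1_010_000, "a")
        b = cm.GenomicInterval("chr1", 1_500_000, 1_510_000, "b")
        truth = cm.SyntheticTruth(hic_true_pairs=[(a, b, 5.0)])
        return a, b, truth

    def test_planted_pair_beats_same_distance_background(self):
        cfg = cm.SimConfig(seed=31)
        a, b, truth = self._planted(cfg)
        cmap = cm.simulate_hic(truth, 10_000, cfg)["chr1"]
        d_planted = abs(a.start // 10_000 - b.start // 10_000)
        same_d = [v for (i, j), v in cmap.entries.items() if j - i == d_planted]
        planted_val = cmap.get(a.start // 10_000, b.start // 10_000)
        assert planted_val > np.percentile(same_d, 95)

    def test_background_signal_decays_with_distance(self):
        cfg = cm.SimConfig(seed=37)
        cmap = cm.simulate_hic(cm.SyntheticTruth(), 10_000, cfg)["chr1"]
        by_d = {}
        for (i, j), v in cmap.entries.items():
            by_d.setdefault(j - i, []).append(v)
        m1 = np.mean(by_d[1])
        m20 = np.mean(by_d[20])
        assert m1 > m20

    def test_seeded_rerun_identical_and_non_negative(self):
        cfg = cm.SimConfig(seed=41)
        _, _, truth = self._planted(cfg)
        m1 = cm.simulate_hic(truth, 10_000, cfg)["chr1"]
        m2 = cm.simulate_hic(truth, 10_000, cfg)["chr1"]
        assert m1.entries == m2.entries
        assert all(v >= 0 for v in m1.entries.values())

    def test_off_chromosome_anchor_rejected(self):
        cfg = cm.SimConfig(seed=43)
        a = cm.GenomicInterval("chr9", 0, 10_000, "a")
        truth = cm.SyntheticTruth(hic_true_pairs=[(a, a, 2.0)])
        with pytest.raises(ValueError):
            cm.simulate_hic(truth, 10_000, cfg)


def test_truth_ledger_ids_resolve(small_dataset):
    d = small_dataset
    cnv_ids = set(d["cnvs"].ids)
    meth_ids = set(d["meth"].ids)
    for p in d["truth"].planted_pairs:
        assert p.variant_id in cnv_ids and p.phenotype_id in meth_ids
    for lp in d["truth"].ld_pairs:
        assert lp.snp_id in set(d["snps"].ids)
    for e in d["truth"].expression_effects:
        assert e.gene_id in set(d["expr"].ids)


def test_planted_and_null_sets_disjoint_enforced():
    with pytest.raises(ValueError):
        cm.SyntheticTruth(
            planted_pairs=[cm.PlantedEffect("v", "c1", 1, 0.5)], null_cpg_ids=["c1"]
        )
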