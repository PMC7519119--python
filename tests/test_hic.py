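import numpy as np
import pytest

import cnvmqtl as cm
from cnvmqtl.hic import HiCContactMap
from cnvmqtl.types import GenomicInterval


class TestIntervalToBins:
    @pytest.mark.parametrize(
        "start,end,res,expected",
        [
            (25_000, 26_000, 10_000, [2]),
            (9_999, 10_001, 10_000, [0, 1]),
            (0, 10_000, 10_000, [0]),
            (10_000, 10_001, 10_000, [1]),
        ],
    )
    def test_floor_arithmetic(self, start, end, res, expected):
        iv = GenomicInterval("chr1", start, end)
        assert list(cm.interval_to_bins(iv, res)) == expected

    def test_invalid_resolution(self):
        with pytest.raises(ValueError):
            cm.interval_to_bins(GenomicInterval("chr1", 0, 100), 0)


class TestContactMap:
    def test_symmetric_access_and_sparse_default(self):
        cmap = HiCContactMap(resolution=10_000, chrom="chr1", entries={(2, 5): 3.5})
        assert cmap.get(2, 5) == 3.5
        assert cmap.get(5, 2) == 3.5
        assert cmap.get(0, 1) == 0.0

    def test_rejects_lower_triangle_and_negative(self):
        with pytest.raises(ValueError):
            HiCContactMap(resolution=10_000, chrom="chr1", entries={(5, 2): 1.0})
        with pytest.raises(ValueError):
            HiCContactMap(resolution=10_000, chrom="chr1", entries={(2, 5): -1.0})


class TestPairSignal:
    def _map(self):
        return HiCContactMap(
            resolution=10_000, chrom="chr1", entries={(10, 50): 7.0, (11, 50): 2.0}
        )

    def test_planted_entry_found(self):
        cnv = GenomicInterval("chr1", 100_000, 110_000, "cnv")  # bin 10
        cpg = GenomicInterval("chr1", 500_000, 500_500, "cpg")  # bin 50
        res = cm.pair_signal(cnv, cpg, 2_000, self._map())
        assert res.nonzero and res.signal == 7.0

    def test_absent_entries_give_zero(self):
        cnv = GenomicInterval("chr1", 200_000, 210_000, "cnv")
        cpg = GenomicInterval("chr1", 900_000, 900_500, "cpg")
        res = cm.pair_signal(cnv, cpg, 2_000, self._map())
        assert not res.nonzero and res.signal == 0.0

    def test_wider_window_never_decreases_signal(self, rng):
        entries = {
            (int(i), int(j)): float(v)
            for i, j, v in zip(
                rng.integers(0, 40, 200), rng.integers(40, 100, 200), rng.random(200)
            )
        }
        cmap = HiCContactMap(resolution=10_000, chrom="chr1", entries=entries)
        for _ in range(50):
            s = int(rng.integers(0, 300_000))
            cnv = GenomicInterval("chr1", s, s + int(rng.integers(1, 50_000)))
            c = int(rng.integers(400_000, 900_000))
            cpg = GenomicInterval("chr1", c, c + 500)
            s2 = cm.pair_signal(cnv, cpg, 2_000, cmap).signal
            s5 = cm.pair_signal(cnv, cpg, 5_000, cmap).signal
            assert s5 >= s2

    def test_inter_chromosomal_rejected(self):
        with pytest.raises(ValueError):
            cm.pair_signal(
                GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 0, 100), 2_000, self._map()
            )


class TestMatchedPairs:
    def _pairs(self, rng, n=30, genome=None):
        genome = genome or {"chr1": 5_000_000, "chr2": 5_000_000}
        out = []
        for i in range(n):
            chrom = "chr1" if i % 2 else "chr2"
            la = int(rng.integers(500, 40_000))
            lb = int(rng.integers(2_000, 12_000))
            a0 = int(rng.integers(0, genome[chrom] - la))
            d = int(rng.integers(30_000, 1_500_000))
            b_mid = min(a0 + la // 2 + d, genome[chrom] - lb // 2 - 1)
            out.append(
                (
                    GenomicInterval(chrom, a0, a0 + la),
                    GenomicInterval(chrom, b_mid - lb // 2, b_mid - lb // 2 + lb),
                )
            )
        return out, genome

    def test_multisets_preserved_exactly(self, rng):
        pairs, genome = self._pairs(rng)
        out = cm.sample_matched_pairs(pairs, genome, seed=5)
        for role in (0, 1):
            assert sorted(p[role].length for p in out) == sorted(p[role].length for p in pairs)
        obs_d = sorted(abs(a.midpoint - b.midpoint) for a, b in pairs)
        out_d = sorted(abs(a.midpoint - b.midpoint) for a, b in out)
        assert obs_d == out_d

    def test_placements_within_bounds_and_seeded(self, rng):
        pairs, genome = self._pairs(rng)
        a = cm.sample_matched_pairs(pairs, genome, seed=6)
        b = cm.sample_matched_pairs(pairs, genome, seed=6)
        assert [(x.start, y.start) for x, y in a] == [(x.start, y.start) for x, y in b]
        for x, y in a:
            assert 0 <= x.start < x.end <= genome[x.chrom]
            assert 0 <= y.start < y.end <= genome[y.chrom]

    def test_oversized_distance_rejected(self):
        pairs = [
            (GenomicInterval("chr1", 0, 1_000), GenomicInterval("chr1", 4_000_000, 4_001_000))
        ]
        with pytest.raises(ValueError):
            cm.sample_matched_pairs(pairs, {"chr1": 2_000_000}, seed=1)


class TestHiCPermutationTest:
    def test_null_invariant_to_pair_order(self, rng, small_cfg):
        pairs, genome = TestMatchedPairs()._pairs(rng, n=20)
        maps = cm.simulate_hic(cm.SyntheticTruth(), 10_000, small_cfg)
        res1 = cm.hic_permutation_test(pairs, maps, genome, iterations=100, seed=9)
        res2 = cm.hic_permutation_test(list(reversed(pairs)), maps, genome, iterations=100, seed=9)
        assert np.array_equal(res1["null_counts"], res2["null_counts"])
        assert res1["p_enrich"] == res2["p_enrich"]

    def test_planted_pairs_hit_estimator_floor(self, small_dataset):
        d = small_dataset
        pairs = [
            (d["cnvs"].interval(p.variant_id), d["meth"].interval(p.phenotype_id))
            for p in d["truth"].planted_pairs
        ]
        d["truth"].hic_true_pairs = [
            (a, cm.GenomicInterval(b.chrom, max(0, b.start - 5_000), b.end + 5_000), 5.0)
            for a, b in pairs
        ]
        maps = cm.simulate_hic(d["truth"], 10_000, d["cfg"])
        d["truth"].hic_true_pairs = []
        res = cm.hic_permutation_test(
            pairs, maps, d["cfg"].chrom_lengths, iterations=200, seed=10
        )
        assert res["observed"] == len(pairs)
        assert res["p_enrich"] == pytest.approx(1 / 201)
        assert np.median(res["log_ratios"]) > 0

    def test_empty_pairs_rejected(self, small_cfg):
        with pytest.raises(ValueError):
            cm.hic_permutation_test({}, {}, {}, iterations=100, seed=1)

    def test_log_ratio_sign_consistent_with_p(self, rng, small_cfg):
        pairs, genome = TestMatchedPairs()._pairs(rng, n=24)
        maps = cm.simulate_hic(cm.SyntheticTruth(), 10_000, small_cfg)
        res = cm.hic_permutation_test(pairs, maps, genome, iterations=200, seed=11)
        med = np.median(res["log_ratios"])
        if res["p_enrich"] < 0.5:
            assert med >= 0
        if med > 0:
            assert res["p_enrich"] <= 0.5 + 1 / 201


def test_refined_map_agrees_on_nonzero_status(small_cfg, rng):
    """A 5 kb map refining a 10 kb map's support gives the same nonzero calls."""
    coarse_entries = {
        (int(i), int(j)): 1.0 + float(v)
        for i, j, v in zip(rng.integers(0, 50, 80), rng.integers(50, 200, 80), rng.random(80))
    }
    coarse = HiCContactMap(resolution=10_000, chrom="chr1", entries=coarse_entries)
    fine_entries = {}
    for (i, j), v in coarse_entries.items():
        for di in (0, 1):
            for dj in (0, 1):
                fine_entries[(2 * i + di, 2 * j + dj)] = v
    fine = HiCContactMap(resolution=5_000, chrom="chr1", entries=fine_entries)
    for _ in range(50):
        s = int(rng.integers(0, 400_000))
        cnv = GenomicInterval("chr1", s, s + int(rng.integers(1_000, 30_000)))
        c = int(rng.integers(500_000, 1_900_000))
        cpg = GenomicInterval("chr1", c, c + 800)
        assert (
            cm.pair_signal(cnv, cpg, 5_000, coarse).nonzero
            == cm.pair_signal(cnv, cpg, 5_000, fine).nonzero
        )
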