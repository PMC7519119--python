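"""Hi-C contact enrichment of CNV-mQTL/CpG pairs.

Plants elevated KR-normalized contact signal at the bin pairs linking each
planted CNV to its associated CpG (with a 5 kb shore window), then tests
whether the pairs hit non-zero contacts more often than size- and
distance-matched random pairs.
"""

import numpy as np

import cnvmqtl as cm

cfg = cm.SimConfig(seed=9, n_cnvs=40, n_cpgs=80)
cnvs = cm.simulate_cnv_genotypes(cfg)
truth = cm.make_truth(cnvs, cfg, n_planted=20)
meth = cm.simulate_methylation(cnvs, truth, cfg)
pairs = [(cnvs.interval(p.variant_id), meth.interval(p.phenotype_id))
         for p in truth.planted_pairs]

truth.hic_true_pairs = [
    (a, cm.GenomicInterval(b.chrom, max(0, b.start - 5000), b.end + 5000), 5.0)
    for a, b in pairs
]
maps = cm.simulate_hic(truth, resolution=10_000, cfg=cfg)

one = cm.pair_signal(*pairs[0], window_bp=5000, cmap=maps[pairs[0][0].chrom])
print(f"example pair {one.cnv_id}/{one.cpg_id}: "
      f"max KR signal={one.signal:.2f} over {len(one.bin_pairs)} bin pairs")

res = cm.hic_permutation_test(pairs, maps, cfg.chrom_lengths, iterations=1000, seed=4)
print(f"pairs with non-zero contact: {res['observed']}/{res['n_pairs']}")
print(f"matched-null mean:           {res['null_counts'].mean():.2f}")
print(f"p_enrich:                    {res['p_enrich']:.4g}")
print(f"median log ratio:            {np.median(res['log_ratios']):.3f}")
print()
print("p_enrich at the 1/1001 floor plus a positive median log ratio says")
print("the real pairs sit on physical contacts far more often than random")
print("pairs with the same sizes and genomic separations.")
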