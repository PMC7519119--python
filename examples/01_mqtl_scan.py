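"""mQTL scan: planted CNV→CpG effects recovered with permutation correction.

Simulates a 77-sample cohort with 10 planted copy-number→methylation effects
(|Spearman rho| targeted at 0.5), scans every same-chromosome CNV/CpG pair,
and calls significance at permutation p < 0.01.
"""

import cnvmqtl as cm

cfg = cm.SimConfig(seed=42, n_samples=77, n_cnvs=40, n_cpgs=120)
cnvs = cm.simulate_cnv_genotypes(cfg)
truth = cm.make_truth(cnvs, cfg, n_planted=10, rho_grid=(0.5,))
meth = cm.simulate_methylation(cnvs, truth, cfg)

scan = cm.ScanConfig(scheme=cm.PermutationScheme(n_perm=1000, seed=1))
records = cm.run_scan(cnvs, meth, scan)
summary = cm.summarize_scan(records, threshold=0.01)

planted = {(p.variant_id, p.phenotype_id) for p in truth.planted_pairs}
called = {(r.variant_id, r.phenotype_id) for r in cm.call_significant(records, 0.01)}

print(f"tested pairs:             {len(records)}")
print(f"significant associations: {summary['n_associations']} "
      f"({summary['n_proximal']} proximal, {summary['n_distal']} distal)")
print(f"unique CNV-mQTLs:         {summary['n_unique_variants']}")
print(f"planted effects found:    {len(called & planted)}/{len(planted)}")
fdr = cm.estimate_fdr(cfg.n_cpgs, 0.01, summary["n_unique_phenotypes"])
print(f"permutation FDR estimate: {100 * fdr:.1f}%")
print()
print("The FDR line is the expected fraction of false CpG calls: CpGs tested")
print("x cutoff / CpGs called.  Recovery close to 10/10 shows the scan's")
print("power at |rho|=0.5 with n=77 and family-wise permutation correction.")
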