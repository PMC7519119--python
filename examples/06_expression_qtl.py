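"""eQTL + eQTM: linking copy number, methylation and expression.

Plants a mediation chain CNV → CpG methylation → gene expression, runs the
CNV-eQTL scan and the eQTM scan (restricted to mQTL-associated CpGs, as the
method prescribes), and intersects the two result sets.
"""

import cnvmqtl as cm

cfg = cm.SimConfig(seed=3, n_samples=77, n_cnvs=30, n_cpgs=60, n_genes=30,
                   noise_scale=0.6)
cnvs = cm.simulate_cnv_genotypes(cfg)
truth = cm.make_truth(cnvs, cfg, n_planted=8, rho_grid=(0.6,),
                      n_meth_driven_genes=4, n_cnv_driven_genes=4)
meth = cm.simulate_methylation(cnvs, truth, cfg)
expr = cm.simulate_expression(meth, cnvs, truth, cfg)

scheme = cm.PermutationScheme(n_perm=1000, seed=6)
mqtl = cm.run_scan(cnvs, meth, cm.ScanConfig(scheme=scheme))
eqtl = cm.run_scan(cnvs, expr, cm.ScanConfig(scan_kind="cnv-eqtl", scheme=scheme))
eqtm = cm.eqtm_scan(meth, expr, mqtl, cm.ScanConfig(scan_kind="eqtm", scheme=scheme))

print(f"significant mQTL associations: {len(cm.call_significant(mqtl, 0.01))}")
print(f"significant eQTL associations: {len(cm.call_significant(eqtl, 0.01))}")
sig_eqtm = cm.call_significant(eqtm, 0.01)
pos = sum(1 for r in sig_eqtm if r.rho > 0)
print(f"significant eQTM associations: {len(sig_eqtm)} "
      f"({pos} positive, {len(sig_eqtm) - pos} negative)")

cpg_gene = {e.mediator_id: e.gene_id for e in truth.expression_effects
            if e.mediator_kind == "cpg"}
report = cm.overlap_mqtl_eqtl(mqtl, eqtl, 0.01, cpg_gene_map=cpg_gene)
print(f"CNVs that are both mQTL and eQTL: {len(report.shared_variants)}")
print(f"same gene on both sides:          {sorted(report.genes_same_both)}")
print()
print("eQTM correlations carry both signs (methylation is not always")
print("repressive at population scale); shared CNVs with the same gene on")
print("the methylation and expression side are mediation-chain candidates.")
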