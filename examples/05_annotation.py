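"""Genomic-context annotation: shores, DMR overlap, genic class, imprinting.

Shows the ±2 kb CpG-island shore construction, the 1 bp-intersection overlap
fraction against an external DMR-style track, genic/non-genic CNV
classification under the biotype priority rule, and imprinted-gene tagging.
"""

import cnvmqtl as cm
from cnvmqtl.types import FeatureTrack, GeneModel, GenomicInterval

islands = FeatureTrack("islands", [
    GenomicInterval("chr1", 10_000, 11_000, "isl1"),
    GenomicInterval("chr1", 13_500, 14_000, "isl2"),  # shores will merge
    GenomicInterval("chr1", 200_000, 201_000, "isl3"),
])
shores = cm.define_shores(islands, flank=2000)
print("island+shore regions:", [(iv.start, iv.end) for iv in shores.intervals])

vmrs = FeatureTrack("vmrs", [
    GenomicInterval("chr1", 12_500, 12_600, "v1"),   # hits merged shore
    GenomicInterval("chr1", 500_000, 500_100, "v2"),
])
count, total, frac = cm.overlap_fraction(vmrs, shores)
print(f"VMRs overlapping island/shore regions: {count}/{total} = {100 * frac:.1f}%")

genes = [
    GeneModel(gene=GenomicInterval("chr1", 9_000, 40_000, "DLK1"), biotype="protein_coding",
              exons=[GenomicInterval("chr1", 9_000, 9_500, "e1")]),
    GeneModel(gene=GenomicInterval("chr1", 190_000, 260_000, "LINC1"), biotype="lncRNA"),
]
for span in [(9_200, 20_000), (195_000, 196_000), (400_000, 401_000)]:
    cnv = GenomicInterval("chr1", *span, id=f"cnv:{span[0]}")
    label = cm.classify_cnv_context(cnv, genes)
    print(f"{cnv.id:12s} -> class={label.context:9s} subgenic={label.subgenic}")

tagged = cm.tag_imprinted(["DLK1", "GSTM1"], {"catalog": ["DLK1", "MEG3"]})
print("imprinted among associated genes:", tagged)
print()
print("The shore merge turns nearby islands into one region; the overlap")
print("fraction is the statistic used for VMR/T-DMR comparisons; the genic")
print("labels follow protein_coding > lncRNA > pseudogene priority.")
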