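"""Genomic-context annotation of mQTL results.

CpG-island shores (±2 kb flanks), overlap fractions against VMR / T-DMR
interval sets, genic vs non-genic CNV classification with a fixed biotype
priority, and imprinted-gene tagging.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import merge_intervals
from .enrichment import count_overlapping
from .types import FeatureTrack, GeneModel, GenomicInterval

BIOTYPE_PRIORITY = ("protein_coding", "lncRNA", "pseudogene")
_CLASS_LABEL = {"protein_coding": "gene", "lncRNA": "lncRNA", "pseudogene": "pseudogene"}


@dataclass(frozen=True)
class ContextLabel:
    cnv_id: str
    context: str  # gene | lncRNA | pseudogene | nongenic
    subgenic: str  # intron | exon | mixed | n/a

    def __post_init__(self):
        if self.context == "nongenic" and self.subgenic != "n/a":
            raise ValueError("non-genic CNVs have no subgenic label")


def define_shores(
    islands: FeatureTrack, flank: int = 2000, genome: dict[str, int] | None = None
) -> FeatureTrack:
    """Island+shore regions: each island extended by ``flank`` bp both ways.

    Clipped at 0 (and at the chromosome end when a genome is given);
    overlapping extended regions are merged.
    """
    extended = []
    for iv in islands.intervals:
        end = iv.end + flank
        if genome and iv.chrom in genome:
            end = min(end, genome[iv.chrom])
        extended.append(GenomicInterval(iv.chrom, max(0, iv.start - flank), end))
    return FeatureTrack(f"{islands.name}_shores", merge_intervals(extended))


def overlap_fraction(
    query: FeatureTrack, subject: FeatureTrack, min_overlap: int = 1
) -> tuple[int, int, float]:
    """(count, total, fraction) of query intervals hitting the subject.

    The 1 bp intersection convention: a query interval counts when it shares
    at least ``min_overlap`` bp with any subject interval.
    """
    if not query.intervals:
        raise ValueError("empty query track")
    count = count_overlapping(query.intervals, subject, min_overlap)
    total = len(query.intervals)
    return count, total, count / total


def classify_cnv_context(cnv: GenomicInterval, genes: list[GeneModel]) -> ContextLabel:
    """Genic/non-genic context of a CNV under the biotype priority rule.

    The class is the highest-priority biotype among overlapping gene models
    (protein_coding > lncRNA > pseudogene), else ``nongenic``.  Subgenic
    structure pools all overlapping models: ``exon`` if only exonic sequence
    is touched, ``intron`` if only intronic span, ``mixed`` when both.
    """
    overlapping = [gm for gm in genes if cnv.overlaps(gm.gene)]
    if not overlapping:
        return ContextLabel(cnv_id=cnv.id, context="nongenic", subgenic="n/a")
    best = min(overlapping, key=lambda gm: BIOTYPE_PRIORITY.index(gm.biotype))
    hit_exon = any(cnv.overlaps(ex) for gm in overlapping for ex in gm.exons)
    hit_intron = False
    for gm in overlapping:
        lo, hi = max(cnv.start, gm.gene.start), min(cnv.end, gm.gene.end)
        exonic = sum(
            max(0, min(hi, ex.end) - max(lo, ex.start)) for ex in merge_intervals(gm.exons)
        ) if gm.exons else 0
        if hi - lo > exonic:
            hit_intron = True
    if hit_exon and hit_intron:
        sub = "mixed"
    elif hit_exon:
        sub = "exon"
    else:
        sub = "intron"
    return ContextLabel(cnv_id=cnv.id, context=_CLASS_LABEL[best.biotype], subgenic=sub)


def tag_imprinted(
    phenotype_genes: list[str], imprinted: dict[str, list[str]] | list[str]
) -> dict[str, list[str]]:
    """Intersect associated gene ids with imprinted-gene catalogs.

    ``imprinted`` is either a flat list or a mapping ``source -> gene ids``;
    ids are case-normalized before matching.  Returns
    ``gene id (original casing) -> sorted list of source catalogs``.
    """
    if isinstance(imprinted, list):
        imprinted = {"imprinted": imprinted}
    norm_catalogs = {
        source: {g.upper() for g in ids} for source, ids in imprinted.items()
    }
    tagged: dict[str, list[str]] = {}
    for gene in phenotype_genes:
        sources = sorted(s for s, ids in norm_catalogs.items() if gene.upper() in ids)
        if sources:
            tagged[gene] = sources
    return tagged


def context_summary(labels: list[ContextLabel]) -> dict:
    """Percentage breakdown of CNV contexts (sums to 100 over any input)."""
    if not labels:
        return {"n": 0}
    n = len(labels)
    out = {"n": n}
    for ctx in ("gene", "lncRNA", "pseudogene", "nongenic"):
        out[f"pct_{ctx}"] = 100.0 * sum(1 for l in labels if l.context == ctx) / n
    for sub in ("exon", "intron", "mixed"):
        out[f"pct_sub_{sub}"] = 100.0 * sum(1 for l in labels if l.subgenic == sub) / n
    return out
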