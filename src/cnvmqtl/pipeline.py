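"""Genome-wide QTL scans: pair selection, batch association, summaries.

The same engine drives three scans:

* ``cnv-mqtl`` — CNV copy-number state vs CpG β-values;
* ``cnv-eqtl`` — CNV copy-number state vs gene expression;
* ``eqtm``     — CpG β-values (variant role) vs gene expression.

For every phenotype, candidate variants on the same chromosome are split
into proximal (the variant interval shares >=1 bp with the 2 Mb window
centred on the phenotype midpoint) and distal (same chromosome, outside the
window); each family is permutation-corrected separately with the
per-phenotype max-|rho| null.  Phenotypes on other chromosomes are never
tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._util import spawn_rng
from .association import (
    AssociationRecord,
    ConstantInputError,
    PermutationScheme,
    call_significant,
    permutation_correct,
    rank_correlation,
)
from .types import GenomicInterval, align_samples

logger = logging.getLogger(__name__)

WINDOW_HALF_WIDTH = 1_000_000  # 1 Mb each side of the phenotype midpoint


@dataclass(frozen=True)
class ScanConfig:
    scan_kind: str = "cnv-mqtl"  # cnv-mqtl | cnv-eqtl | eqtm
    window_half_width: int = WINDOW_HALF_WIDTH
    threshold: float = 0.01
    scheme: PermutationScheme = field(default_factory=PermutationScheme)
    min_maf: float = 0.0  # annotate-only by default; set >0 to filter variants

    def __post_init__(self):
        if self.window_half_width <= 0:
            raise ValueError("window_half_width must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.scan_kind not in ("cnv-mqtl", "cnv-eqtl", "eqtm"):
            raise ValueError(f"unknown scan kind {self.scan_kind!r}")


@dataclass
class OverlapReport:
    """Cross-scan intersections between mQTL and eQTL results."""

    shared_variants: set[str]
    genes_same_both: set[str]
    genes_expr_assoc: set[str]


def classify_pairing(
    variant: GenomicInterval, phenotype_site: GenomicInterval, cfg: ScanConfig | None = None
) -> str:
    """proximal | distal | untested for one variant/phenotype pair.

    Proximal means the variant interval overlaps the window
    ``[midpoint - w, midpoint + w)`` by at least 1 bp (window-straddling
    CNVs count); distal means same chromosome but no overlap; different
    chromosomes are untested.
    """
    half = cfg.window_half_width if cfg else WINDOW_HALF_WIDTH
    if variant.chrom != phenotype_site.chrom:
        return "untested"
    mid = phenotype_site.midpoint
    win_lo, win_hi = mid - half, mid + half
    if variant.start < win_hi and variant.end > win_lo:
        return "proximal"
    return "distal"


def run_scan(genotypes, phenotypes, cfg: ScanConfig | None = None) -> list[AssociationRecord]:
    """Test every same-chromosome variant/phenotype pair.

    ``genotypes`` plays the variant role (a GenotypeMatrix, or a
    MethylationMatrix for the eQTM scan); ``phenotypes`` is a Methylation- or
    ExpressionMatrix.  Samples are aligned by id intersection in genotype
    order.  Constant phenotype rows and rows monomorphic after alignment are
    skipped with a logged count.  Each phenotype's proximal and distal
    families are permutation-corrected separately, with a per-phenotype
    seeded stream so results do not depend on phenotype order.
    """
    cfg = cfg or ScanConfig()
    genotypes, phenotypes = align_samples(genotypes, phenotypes)
    if len(genotypes.samples) < 3:
        raise ValueError("need at least 3 shared samples")

    if cfg.min_maf > 0 and hasattr(genotypes, "maf"):
        maf = genotypes.maf()
        keep = [iv.id for iv, m in zip(genotypes.rows, maf) if m >= cfg.min_maf]
        genotypes = genotypes.subset_rows(keep)

    records: list[AssociationRecord] = []
    n_skipped = 0
    for p_idx, site in enumerate(phenotypes.rows):
        y = phenotypes.values[p_idx]
        if np.all(y == y[0]):
            n_skipped += 1
            continue
        families: dict[str, list[int]] = {"proximal": [], "distal": []}
        for v_idx, variant in enumerate(genotypes.rows):
            mode = classify_pairing(variant, site, cfg)
            if mode == "untested" or variant.id == site.id:
                continue
            row = genotypes.values[v_idx]
            ok = ~np.isnan(row)
            if ok.sum() < 3 or np.all(row[ok] == row[ok][0]):
                n_skipped += 1
                continue
            families[mode].append(v_idx)
        for mode, idx in families.items():
            if not idx:
                continue
            rows = genotypes.values[idx]
            rng = spawn_rng(cfg.scheme.seed, "perm", site.id, mode)
            perm_p = permutation_correct(y, rows, cfg.scheme, rng=rng)
            for k, v_idx in enumerate(idx):
                variant = genotypes.rows[v_idx]
                rho, nominal_p = rank_correlation(genotypes.values[v_idx], y)
                records.append(
                    AssociationRecord(
                        variant_id=variant.id,
                        phenotype_id=site.id,
                        rho=rho,
                        nominal_p=nominal_p,
                        perm_p=float(perm_p[k]),
                        mode=mode,
                        distance=variant.midpoint - site.midpoint,
                    )
                )
    if n_skipped:
        logger.info("scan skipped %d constant/monomorphic rows or pairs", n_skipped)
    return records


def eqtm_scan(meth, expr, mqtl_records, cfg: ScanConfig | None = None, threshold: float = 0.01):
    """Methylation→expression scan restricted to mQTL-associated CpGs."""
    cfg = cfg or ScanConfig(scan_kind="eqtm")
    sig_cpgs = {r.phenotype_id for r in call_significant(mqtl_records, threshold)}
    keep = [iv.id for iv in meth.rows if iv.id in sig_cpgs]
    if not keep:
        return []
    return run_scan(meth.subset_rows(keep), expr, cfg)


def summarize_scan(records, threshold: float = 0.01, *, hist_bin_bp: int = 1_000_000) -> dict:
    """Headline counts and a |distance| histogram for significant records."""
    sig = call_significant(records, threshold)
    prox = [r for r in sig if r.mode == "proximal"]
    dist = [r for r in sig if r.mode == "distal"]
    prox_vars = {r.variant_id for r in prox}
    dist_vars = {r.variant_id for r in dist}
    distances = np.abs(np.array([r.distance for r in sig], dtype=float))
    if len(distances):
        top = (int(distances.max()) // hist_bin_bp + 1) * hist_bin_bp
        counts, edges = np.histogram(distances, bins=np.arange(0, top + 1, hist_bin_bp))
    else:
        counts, edges = np.array([], dtype=int), np.array([0])
    return {
        "n_associations": len(sig),
        "n_proximal": len(prox),
        "n_distal": len(dist),
        "n_unique_variants": len(prox_vars | dist_vars),
        "n_unique_phenotypes": len({r.phenotype_id for r in sig}),
        "n_both_mode_variants": len(prox_vars & dist_vars),
        "distance_hist_counts": counts.tolist(),
        "distance_hist_edges_bp": edges.tolist(),
    }


def overlap_mqtl_eqtl(
    mqtl_records,
    eqtl_records,
    threshold: float = 0.01,
    *,
    cpg_gene_map: dict[str, str] | None = None,
) -> OverlapReport:
    """CNVs significant in both the mQTL and eQTL scans, and shared genes.

    ``cpg_gene_map`` maps CpG phenotype ids to gene ids so "methylation and
    expression of the same gene" can be joined; without it, the CpG id
    itself is used as the gene label.
    """
    mqtl_universe = {r.variant_id for r in mqtl_records}
    eqtl_universe = {r.variant_id for r in eqtl_records}
    if mqtl_records and eqtl_records and not (mqtl_universe & eqtl_universe):
        raise ValueError("mQTL and eQTL scans share no variants: mismatched universes")
    sig_m = call_significant(mqtl_records, threshold)
    sig_e = call_significant(eqtl_records, threshold)
    shared = {r.variant_id for r in sig_m} & {r.variant_id for r in sig_e}

    def gene_of(cpg_id: str) -> str:
        return cpg_gene_map.get(cpg_id, cpg_id) if cpg_gene_map else cpg_id

    genes_same_both = set()
    for v in shared:
        meth_genes = {gene_of(r.phenotype_id) for r in sig_m if r.variant_id == v}
        expr_genes = {r.phenotype_id for r in sig_e if r.variant_id == v}
        genes_same_both |= meth_genes & expr_genes
    genes_expr_assoc = {r.phenotype_id for r in sig_e if r.variant_id in shared}
    return OverlapReport(
        shared_variants=shared,
        genes_same_both=genes_same_both,
        genes_expr_assoc=genes_expr_assoc,
    )


def replicate_scan(
    discovery_records,
    genotypes,
    phenotypes,
    cfg: ScanConfig | None = None,
    *,
    discovery_threshold: float = 0.01,
) -> dict:
    """Validation-cohort mode: re-scan only discovery-significant variants.

    Reports replication of discovery (variant, phenotype) pairs at both the
    strict (0.01) and relaxed (0.05) permutation thresholds in the new
    cohort.
    """
    cfg = cfg or ScanConfig()
    sig = call_significant(discovery_records, discovery_threshold)
    if not sig:
        raise ValueError("no significant discovery associations to replicate")
    var_ids = [iv.id for iv in genotypes.rows if iv.id in {r.variant_id for r in sig}]
    if not var_ids:
        raise ValueError("no discovery variants present in validation genotypes")
    records = run_scan(genotypes.subset_rows(var_ids), phenotypes, cfg)
    disc_pairs = {(r.variant_id, r.phenotype_id) for r in sig}
    out = {"n_discovery_pairs": len(disc_pairs), "records": records}
    for label, thr in (("p01", 0.01), ("p05", 0.05)):
        rep = {
            (r.variant_id, r.phenotype_id)
            for r in call_significant(records, thr)
        } & disc_pairs
        out[f"n_replicated_{label}"] = len(rep)
        out[f"fraction_replicated_{label}"] = len(rep) / len(disc_pairs)
    return out
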