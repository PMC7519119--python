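"""LD between CNVs and SNPs, best-tag selection, and conditional re-testing.

LD is the squared Pearson correlation of genotype vectors.  The conditional
analysis asks whether a CNV keeps an independent effect on CpG methylation
once nearby SNP-mQTL genotypes are accounted for: the rank-transformed
β-vector is regressed on the SNP covariates plus the CNV state, and the CNV
coefficient's two-sided t-test p decides independence at the 0.05 rule.  The
rank transform keeps the test aligned with the Spearman scan that produced
the candidate associations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .types import GenomicInterval, GenotypeMatrix


@dataclass(frozen=True)
class LDRecord:
    cnv_id: str
    snp_id: str
    r2: float
    distance: int  # closest gap between the SNP position and the CNV interval

    def __post_init__(self):
        if not -1e-12 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError(f"r2 out of range: {self.r2}")


@dataclass(frozen=True)
class ConditionalResult:
    cnv_id: str
    cpg_id: str
    covariate_snp_ids: tuple[str, ...]
    conditional_p: float
    independent: bool
    identifiable: bool = True


def ld_r2(a, b) -> float:
    """Squared Pearson correlation between two genotype vectors.

    Missing entries are dropped pairwise-complete; constant vectors raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant genotype vector: LD undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _snp_gap(cnv: GenomicInterval, snp: GenomicInterval) -> int:
    """Closest gap between the SNP start position and the CNV interval ends."""
    pos = snp.start
    if cnv.start <= pos < cnv.end:
        return 0
    return pos - cnv.end + 1 if pos >= cnv.end else cnv.start - pos


def best_tag_snp(
    cnv: GenomicInterval, snps: GenotypeMatrix, cnv_genotypes: np.ndarray, window: int = 1_000_000
) -> LDRecord | None:
    """Highest-r² SNP within ``window`` bp of the CNV interval, or None.

    Exact r² ties break toward the lower-coordinate SNP.  SNPs constant in
    the shared samples are ignored.
    """
    best: LDRecord | None = None
    order = sorted(range(len(snps.rows)), key=lambda i: (snps.rows[i].chrom, snps.rows[i].start))
    for i in order:
        snp = snps.rows[i]
        if snp.chrom != cnv.chrom:
            continue
        gap = _snp_gap(cnv, snp)
        if gap > window:
            continue
        try:
            r2 = ld_r2(cnv_genotypes, snps.values[i])
        except ValueError:
            continue
        if best is None or r2 > best.r2 + 1e-15:
            best = LDRecord(cnv_id=cnv.id, snp_id=snp.id, r2=r2, distance=gap)
    return best


def conditional_association(
    cpg_beta,
    cnv,
    snp_covariates=None,
    *,
    cnv_id: str = "cnv",
    cpg_id: str = "cpg",
    covariate_ids: tuple[str, ...] = (),
    alpha: float = 0.05,
    rank_transform: bool = True,
) -> ConditionalResult:
    """Test the CNV's effect on methylation conditional on SNP covariates.

    Fits OLS of the (rank-transformed) β-vector on [intercept, SNPs..., CNV]
    and reports the CNV coefficient's two-sided p.  A CNV collinear with its
    covariates (r² = 1 on the fitted design) is flagged non-identifiable and
    called dependent.  With no covariates this reduces to the marginal
    linear-model test.
    """
    y = np.asarray(cpg_beta, dtype=float)
    g = np.asarray(cnv, dtype=float)
    covs = [np.asarray(c, dtype=float) for c in (snp_covariates or [])]
    n = y.size
    if g.size != n or any(c.size != n for c in covs):
        raise ValueError("all vectors must share the sample dimension")
    if n < len(covs) + 3:
        raise ValueError("too few samples for the requested covariate count")
    if np.all(g == g[0]):
        raise ValueError("constant CNV vector")
    if rank_transform:
        y = stats.rankdata(y)

    design = np.column_stack([np.ones(n)] + covs) if covs else np.ones((n, 1))
    full = np.column_stack([design, g])
    # identifiability: the CNV must add rank beyond the covariate space
    if np.linalg.matrix_rank(full) <= np.linalg.matrix_rank(design):
        return ConditionalResult(
            cnv_id=cnv_id,
            cpg_id=cpg_id,
            covariate_snp_ids=tuple(covariate_ids),
            conditional_p=1.0,
            independent=False,
            identifiable=False,
        )
    fit = sm.OLS(y, full).fit()
    p = float(fit.pvalues[-1])
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return ConditionalResult(
        cnv_id=cnv_id,
        cpg_id=cpg_id,
        covariate_snp_ids=tuple(covariate_ids),
        conditional_p=p,
        independent=p < alpha,
    )


def conditional_scan(
    meth,
    cnvs: GenotypeMatrix,
    snps: GenotypeMatrix,
    associations,
    *,
    window: int = 1_000_000,
    max_covariates: int = 10,
    alpha: float = 0.05,
) -> list[ConditionalResult]:
    """Run the conditional test for each significant CNV-CpG association.

    For every association, SNPs within ``window`` bp of the CNV are entered
    jointly as covariates (strongest r² first, capped at
    ``max_covariates`` to avoid overfitting at small n).
    """
    results = []
    for rec in associations:
        cnv_iv = cnvs.interval(rec.variant_id)
        g = cnvs.row(rec.variant_id)
        scored = []
        for i, snp in enumerate(snps.rows):
            if snp.chrom != cnv_iv.chrom or _snp_gap(cnv_iv, snp) > window:
                continue
            try:
                scored.append((ld_r2(g, snps.values[i]), snp.id, snps.values[i]))
            except ValueError:
                continue
        scored.sort(key=lambda t: (-t[0], t[1]))
        chosen = scored[:max_covariates]
        results.append(
            conditional_association(
                meth.row(rec.phenotype_id),
                g,
                [c[2] for c in chosen],
                cnv_id=rec.variant_id,
                cpg_id=rec.phenotype_id,
                covariate_ids=tuple(c[1] for c in chosen),
                alpha=alpha,
            )
        )
    return results
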