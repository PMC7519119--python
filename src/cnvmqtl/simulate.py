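"""Seeded synthetic-data generators with planted, recoverable structure.

The generators emulate the inputs of a CNV-methylation QTL study: diploid
copy-number genotypes across a minor-allele-frequency spectrum, SNPs in
tunable LD with chosen CNVs, CpG β-values with planted monotone copy-number
effects at chosen Spearman targets (plus pure-noise null sites), expression
driven by methylation or copy number, interval tracks with tunable placement
bias, and sparse distance-decaying Hi-C contact maps with planted high-signal
anchor pairs.  Every planted effect is recorded in a :class:`SyntheticTruth`
ledger so recovery can be scored exactly.

All generators are pure functions of ``(cfg, truth)``: the global seed feeds
a per-generator stream, so each data type can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from ._util import spawn_rng
from .types import (
    ExpressionMatrix,
    FeatureTrack,
    GenomicInterval,
    GenotypeMatrix,
    MethylationMatrix,
)


@dataclass(frozen=True)
class PlantedEffect:
    """One planted CNV→CpG effect."""

    variant_id: str
    phenotype_id: str
    sign: int  # +1 or -1
    rho: float  # target |Spearman|
    mode: str = "proximal"  # where the CpG is placed relative to the CNV

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise ValueError("sign must be ±1")
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("target rho magnitude must be in (0, 1]")


@dataclass(frozen=True)
class ExpressionEffect:
    """A gene driven by a CpG's methylation or a CNV's copy number."""

    gene_id: str
    mediator_id: str
    mediator_kind: str  # "cpg" | "cnv"
    sign: int
    strength: float = 1.0


@dataclass(frozen=True)
class LDPair:
    cnv_id: str
    snp_id: str
    r2: float

    def __post_init__(self):
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("target r2 must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ledger of everything planted; sufficient to score recovery."""

    planted_pairs: list[PlantedEffect] = field(default_factory=list)
    null_cpg_ids: list[str] = field(default_factory=list)
    ld_pairs: list[LDPair] = field(default_factory=list)
    expression_effects: list[ExpressionEffect] = field(default_factory=list)
    null_gene_ids: list[str] = field(default_factory=list)
    enriched_tracks: dict[str, float] = field(default_factory=dict)
    hic_true_pairs: list[tuple[GenomicInterval, GenomicInterval, float]] = field(
        default_factory=list
    )

    def __post_init__(self):
        planted = {p.phenotype_id for p in self.planted_pairs}
        if planted & set(self.null_cpg_ids):
            raise ValueError("planted and null CpG id sets must be disjoint")


@dataclass
class SimConfig:
    """Study-scale knobs for the synthetic cohort.

    Defaults mirror the discovery-cohort scale the method is meant for
    (77 individuals) shrunk onto two 5 Mb desk-scale chromosomes.
    """

    seed: int
    n_samples: int = 77
    n_cnvs: int = 50
    n_cpgs: int = 200
    n_snps: int = 50
    n_genes: int = 50
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_grid: tuple[float, ...] = (0.3, 0.4, 0.5)
    noise_scale: float = 1.0
    cnv_size_range: tuple[int, int] = (500, 50_000)
    cpg_size_range: tuple[int, int] = (200, 1_000)
    feature_size: int = 200
    hic_alpha: float = 1.0  # contact-decay exponent
    hic_amp: float = 10.0  # contact amplitude at distance 0
    hic_density: float = 2.0  # sparsity: P(entry at bin distance d) = min(1, density/(1+d))
    hic_boost: float = 10.0  # planted-pair signal multiplier over background

    def __post_init__(self):
        for name in ("n_samples", "n_cnvs", "n_cpgs", "n_snps", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _random_interval(rng, chrom: str, chrom_len: int, size_range: tuple[int, int], iid: str):
    lo, hi = size_range
    hi = min(hi, chrom_len)
    size = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    size = max(1, min(size, chrom_len - 1))
    start = int(rng.integers(0, chrom_len - size))
    return GenomicInterval(chrom, start, start + size, iid)


def simulate_cnv_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Diploid copy-number states in {0..4} across an MAF spectrum.

    Each variant is a deletion or a duplication polymorphism: the state is
    ``2 ± Binomial(2, p)`` with the non-reference allele frequency ``p``
    drawn uniformly from ``cfg.maf_range``.  Monomorphic draws are rejected
    so every variant is polymorphic in the cohort.
    """
    if cfg.n_samples < 3:
        raise ValueError("need at least 3 samples for downstream correlation")
    rng = spawn_rng(cfg.seed, "cnv")
    chroms = list(cfg.chrom_lengths)
    variants, rows = [], []
    for i in range(cfg.n_cnvs):
        chrom = chroms[int(rng.integers(len(chroms)))]
        iv = _random_interval(rng, chrom, cfg.chrom_lengths[chrom], cfg.cnv_size_range, f"cnv{i:04d}")
        direction = -1 if rng.random() < 0.5 else 1
        p = rng.uniform(*cfg.maf_range)
        for _ in range(1000):
            alleles = rng.binomial(2, p, size=cfg.n_samples)
            if len(np.unique(alleles)) > 1:
                break
        else:
            raise RuntimeError("could not draw a polymorphic variant")
        variants.append(iv)
        rows.append(2 + direction * alleles)
    samples = [f"S{j:03d}" for j in range(cfg.n_samples)]
    return GenotypeMatrix(variants, samples, np.array(rows, dtype=float))


def make_truth(
    cnvs: GenotypeMatrix,
    cfg: SimConfig,
    *,
    n_planted: int = 20,
    n_ld_pairs: int = 10,
    n_meth_driven_genes: int = 5,
    n_cnv_driven_genes: int = 5,
    rho_grid: tuple[float, ...] | None = None,
    modes: tuple[str, ...] = ("proximal", "distal"),
) -> SyntheticTruth:
    """Assemble a truth ledger against a generated CNV matrix.

    Planted CNV→CpG pairs cycle through ``rho_grid`` (default the config's
    effect grid), alternate signs and proximal/distal placement; the first
    methylation-driven expression genes are wired to planted CpGs so the
    CNV→CpG→gene mediation chain is recoverable.
    """
    if n_planted > cfg.n_cpgs:
        raise ValueError("more planted pairs than CpG sites")
    rho_grid = tuple(rho_grid or cfg.effect_grid)
    rng = spawn_rng(cfg.seed, "truth")
    cnv_ids = [iv.id for iv in cnvs.variants]
    chosen = rng.choice(len(cnv_ids), size=min(n_planted, len(cnv_ids)), replace=False)
    planted = [
        PlantedEffect(
            variant_id=cnv_ids[int(c)],
            phenotype_id=f"cpg{k:04d}",
            sign=1 if k % 2 == 0 else -1,
            rho=rho_grid[k % len(rho_grid)],
            mode=modes[k % len(modes)],
        )
        for k, c in enumerate(chosen)
    ]
    null_cpgs = [f"cpg{k:04d}" for k in range(len(planted), cfg.n_cpgs)]
    ld_cnvs = rng.choice(len(cnv_ids), size=min(n_ld_pairs, len(cnv_ids)), replace=False)
    r2_grid = (1.0, 0.8, 0.5, 0.2)
    ld_pairs = [
        LDPair(cnv_ids[int(c)], f"snp{k:04d}", r2_grid[k % len(r2_grid)])
        for k, c in enumerate(ld_cnvs)
    ]
    expr_effects = []
    gene_idx = 0
    for k in range(min(n_meth_driven_genes, len(planted))):
        expr_effects.append(
            ExpressionEffect(
                gene_id=f"gene{gene_idx:04d}",
                mediator_id=planted[k].phenotype_id,
                mediator_kind="cpg",
                sign=1 if k % 2 == 0 else -1,
            )
        )
        gene_idx += 1
    for k in range(n_cnv_driven_genes):
        expr_effects.append(
            ExpressionEffect(
                gene_id=f"gene{gene_idx:04d}",
                mediator_id=cnv_ids[int(chosen[k % len(chosen)])],
                mediator_kind="cnv",
                sign=1 if k % 2 == 0 else -1,
            )
        )
        gene_idx += 1
    null_genes = [f"gene{k:04d}" for k in range(gene_idx, cfg.n_genes)]
    return SyntheticTruth(
        planted_pairs=planted,
        null_cpg_ids=null_cpgs,
        ld_pairs=ld_pairs,
        expression_effects=expr_effects,
        null_gene_ids=null_genes,
    )


def _mean_abs_spearman(state: np.ndarray, scale: float, noise: float, rng, n_rep: int = 200):
    z = (state - state.mean()) / state.std()
    eps = rng.normal(0.0, 1.0, size=(n_rep, state.size))
    y = scale * z[None, :] + noise * eps
    ry = stats.rankdata(y, axis=1)
    rz = stats.rankdata(state)
    rz = rz - rz.mean()
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = ry @ rz
    den = np.linalg.norm(ry, axis=1) * np.linalg.norm(rz)
    return float(np.mean(np.abs(num / den)))


def _calibrate_effect(state: np.ndarray, target_rho: float, noise: float, rng) -> float:
    """Find the linear effect scale whose expected |Spearman| hits the target.

    Empirical bisection on pilot draws (the generative model has no closed
    form for Spearman against a discrete genotype).  Seeded from the caller
    so the lookup is reproducible.
    """
    if noise == 0:
        return 1.0
    # analytic warm start from the bivariate-normal approximation
    r_p = 2 * math.sin(math.pi * min(target_rho, 0.999) / 6)
    lo, hi = 0.0, 4 * noise * r_p / math.sqrt(1 - r_p**2) + 1.0
    while _mean_abs_spearman(state, hi, noise, spawn_rng(int(rng.integers(2**31)), "cal")) < target_rho:
        hi *= 2
        if hi > 1e4:
            return hi  # target beyond what ties in the genotype allow
    pilot_rng = spawn_rng(int(rng.integers(2**31)), "pilot")
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if _mean_abs_spearman(state, mid, noise, pilot_rng) < target_rho:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _logistic(x):
    from scipy.special import expit

    return expit(x)


def _place_relative(rng, anchor: GenomicInterval, chrom_len: int, mode: str, size: int):
    """Place a phenotype interval proximal or distal to an anchor CNV.

    Proximal: the anchor overlaps the 2 Mb window centred on the phenotype
    midpoint.  Distal: same chromosome, anchor fully outside that window.
    """
    half = 1_000_000
    for _ in range(1000):
        if mode == "proximal":
            mid = anchor.midpoint + int(rng.integers(-half // 2, half // 2))
        else:
            gap = half + anchor.length + 50_000
            offset = gap + int(rng.integers(0, half))
            mid = anchor.midpoint + (offset if rng.random() < 0.5 else -offset)
        start = mid - size // 2
        if start < 0 or start + size > chrom_len:
            continue
        iv = GenomicInterval(anchor.chrom, start, start + size)
        win_lo, win_hi = iv.midpoint - half, iv.midpoint + half
        overlap = anchor.start < win_hi and anchor.end > win_lo
        if (mode == "proximal") == overlap:
            return iv
    raise RuntimeError(f"could not place a {mode} phenotype near {anchor.id}")


def simulate_methylation(
    cnvs: GenotypeMatrix, truth: SyntheticTruth, cfg: SimConfig
) -> MethylationMatrix:
    """β-values with planted monotone copy-number effects.

    Planted sites follow ``beta = logistic(a·z + noise_scale·eps)`` with
    ``z`` the standardized copy-number state and ``a`` calibrated so the
    expected |Spearman| with the genotype tracks the target magnitude; null
    sites are ``logistic(eps)`` pure noise.  All β-values land in (0, 1) by
    construction, and CpG coordinates realize each planted pair's
    proximal/distal label.
    """
    for p in truth.planted_pairs:
        if p.rho > 1:
            raise ValueError("effect magnitude above 1")
        if p.variant_id not in {iv.id for iv in cnvs.variants}:
            raise KeyError(f"planted variant {p.variant_id} not in genotype matrix")
    rng = spawn_rng(cfg.seed, "meth")
    chroms = list(cfg.chrom_lengths)
    n = len(cnvs.samples)
    sites, rows = [], []
    for p in truth.planted_pairs:
        state = cnvs.row(p.variant_id)
        a = _calibrate_effect(state, p.rho, cfg.noise_scale, rng)
        z = (state - state.mean()) / state.std()
        eps = rng.normal(0.0, 1.0, size=n)
        beta = _logistic(p.sign * a * z + cfg.noise_scale * eps)
        anchor = cnvs.interval(p.variant_id)
        size = int(rng.integers(*cfg.cpg_size_range))
        iv = _place_relative(rng, anchor, cfg.chrom_lengths[anchor.chrom], p.mode, size)
        sites.append(GenomicInterval(iv.chrom, iv.start, iv.end, p.phenotype_id))
        rows.append(beta)
    for cid in truth.null_cpg_ids:
        chrom = chroms[int(rng.integers(len(chroms)))]
        iv = _random_interval(rng, chrom, cfg.chrom_lengths[chrom], cfg.cpg_size_range, cid)
        sites.append(iv)
        rows.append(_logistic(rng.normal(0.0, 1.0, size=n)))
    return MethylationMatrix(sites, cnvs.samples, np.array(rows))


def simulate_snps_in_ld(
    cnvs: GenotypeMatrix, truth: SyntheticTruth, cfg: SimConfig
) -> GenotypeMatrix:
    """Biallelic SNP dosages, some in calibrated LD with chosen CNVs.

    A paired SNP starts as the CNV's non-reference allele dosage
    ``min(|state−2|, 2)``; each of its two allele slots is then re-drawn from
    the population frequency at an error rate chosen so the realized Pearson
    r² approximates the target (several candidate draws are generated and the
    closest kept).  Unpaired SNPs are independent ``Binomial(2, maf)`` draws.
    Paired SNPs are placed within 1 Mb of their CNV.
    """
    rng = spawn_rng(cfg.seed, "snp")
    cnv_ids = {iv.id for iv in cnvs.variants}
    for lp in truth.ld_pairs:
        if lp.cnv_id not in cnv_ids:
            raise KeyError(f"LD pair references unknown CNV {lp.cnv_id}")
    n = len(cnvs.samples)
    chroms = list(cfg.chrom_lengths)
    snps, rows = [], []
    paired = {lp.snp_id: lp for lp in truth.ld_pairs}
    for i in range(cfg.n_snps):
        sid = f"snp{i:04d}"
        if sid in paired:
            lp = paired[sid]
            dosage = np.minimum(np.abs(cnvs.row(lp.cnv_id) - 2), 2)
            if len(np.unique(dosage)) < 2:
                raise ValueError(f"CNV {lp.cnv_id} monomorphic after recoding; cannot tag")
            if lp.r2 == 1.0:
                snp = dosage.copy()
            else:
                p_hat = dosage.mean() / 2
                q = 1.0 - math.sqrt(lp.r2)
                best, best_gap = None, np.inf
                for _ in range(25):
                    cand = dosage.copy()
                    for allele in range(2):
                        err = rng.random(n) < q
                        had = (dosage >= allele + 1).astype(float)
                        new = np.where(err, rng.binomial(1, p_hat, size=n), had)
                        cand = cand - had + new
                    if len(np.unique(cand)) < 2:
                        continue
                    realized = np.corrcoef(dosage, cand)[0, 1] ** 2
                    gap = abs(realized - lp.r2)
                    if gap < best_gap:
                        best, best_gap = cand, gap
                if best is None:
                    raise RuntimeError(f"could not generate SNP in LD with {lp.cnv_id}")
                snp = best
            anchor = cnvs.interval(lp.cnv_id)
            pos = int(
                np.clip(
                    anchor.midpoint + rng.integers(-1_000_000, 1_000_000),
                    0,
                    cfg.chrom_lengths[anchor.chrom] - 2,
                )
            )
            iv = GenomicInterval(anchor.chrom, pos, pos + 1, sid)
        else:
            maf = rng.uniform(*cfg.maf_range)
            for _ in range(1000):
                snp = rng.binomial(2, maf, size=n).astype(float)
                if len(np.unique(snp)) > 1:
                    break
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(0, cfg.chrom_lengths[chrom] - 1))
            iv = GenomicInterval(chrom, pos, pos + 1, sid)
        snps.append(iv)
        rows.append(np.asarray(snp, dtype=float))
    return GenotypeMatrix(snps, cnvs.samples, np.array(rows))


def simulate_expression(
    meth: MethylationMatrix,
    cnvs: GenotypeMatrix,
    truth: SyntheticTruth,
    cfg: SimConfig,
) -> ExpressionMatrix:
    """Non-negative expression: methylation-driven, CNV-driven, or null.

    Driven genes follow ``expr = exp(sign·strength·z + noise·eps)`` with
    ``z`` the standardized mediator (a CpG's β or a CNV state) — monotone in
    the mediator with either sign; null genes are log-normal noise.  Genes
    are placed within 1 Mb of their mediator so the planted chain is
    proximal.
    """
    rng = spawn_rng(cfg.seed, "expr")
    n = len(meth.samples)
    chroms = list(cfg.chrom_lengths)
    genes, rows = [], []
    cpg_ids = set(meth.ids)
    cnv_ids = {iv.id for iv in cnvs.variants}
    for eff in truth.expression_effects:
        if eff.mediator_kind == "cpg":
            if eff.mediator_id not in cpg_ids:
                raise KeyError(f"unknown CpG mediator {eff.mediator_id}")
            v = meth.row(eff.mediator_id)
            anchor = meth.interval(eff.mediator_id)
        elif eff.mediator_kind == "cnv":
            if eff.mediator_id not in cnv_ids:
                raise KeyError(f"unknown CNV mediator {eff.mediator_id}")
            v = cnvs.row(eff.mediator_id)
            anchor = cnvs.interval(eff.mediator_id)
        else:
            raise ValueError(f"unknown mediator kind {eff.mediator_kind!r}")
        z = (v - v.mean()) / v.std()
        eps = rng.normal(0.0, 1.0, size=n)
        expr = np.exp(eff.sign * eff.strength * z + cfg.noise_scale * eps)
        mid = anchor.midpoint + int(rng.integers(-500_000, 500_000))
        mid = int(np.clip(mid, 1_000, cfg.chrom_lengths[anchor.chrom] - 2_000))
        genes.append(GenomicInterval(anchor.chrom, mid - 500, mid + 500, eff.gene_id))
        rows.append(expr)
    for gid in truth.null_gene_ids:
        chrom = chroms[int(rng.integers(len(chroms)))]
        iv = _random_interval(rng, chrom, cfg.chrom_lengths[chrom], (500, 5_000), gid)
        genes.append(iv)
        rows.append(np.exp(rng.normal(0.0, 1.0, size=n)))
    return ExpressionMatrix(genes, meth.samples, np.array(rows))


def simulate_feature_track(
    regions_of_interest: list[GenomicInterval],
    bias: float,
    cfg: SimConfig,
    *,
    n_features: int = 1000,
    name: str = "track",
) -> FeatureTrack:
    """Features placed uniformly, with probability mass ×``bias`` inside ROIs.

    ``bias=1`` is genome-uniform; ``bias>1`` enriches inside the regions of
    interest; ``0<=bias<1`` depletes them (``bias=0`` excludes placement
    entirely).  Feature length is ``cfg.feature_size``.
    """
    if bias < 0:
        raise ValueError("bias must be non-negative")
    genome_bp = sum(cfg.chrom_lengths.values())
    if genome_bp <= 0:
        raise ValueError("empty genome")
    from ._util import merge_intervals

    rois = merge_intervals([iv for iv in regions_of_interest if iv.chrom in cfg.chrom_lengths])
    # complement segments so "outside" draws never land inside the ROIs
    complement: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in rois:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, length in cfg.chrom_lengths.items():
        cursor = 0
        for iv in sorted(by_chrom.get(chrom, []), key=lambda x: x.start):
            if iv.start > cursor:
                complement.append(GenomicInterval(chrom, cursor, iv.start))
            cursor = max(cursor, iv.end)
        if cursor < length:
            complement.append(GenomicInterval(chrom, cursor, length))
    roi_bp = sum(iv.length for iv in rois)
    out_bp = sum(iv.length for iv in complement)
    p_inside = bias * roi_bp / (bias * roi_bp + out_bp) if roi_bp else 0.0

    def _sample_mid(rng, segments, cum):
        offset = int(rng.integers(cum[-1]))
        k = int(np.searchsorted(cum, offset, side="right"))
        seg = segments[k]
        return seg.chrom, seg.start + offset - int(cum[k - 1] if k else 0)

    roi_cum = np.cumsum([iv.length for iv in rois]) if rois else None
    out_cum = np.cumsum([iv.length for iv in complement]) if complement else None
    rng = spawn_rng(cfg.seed, "track", name)
    size = cfg.feature_size
    intervals = []
    for i in range(n_features):
        if roi_cum is not None and rng.random() < p_inside:
            chrom, mid = _sample_mid(rng, rois, roi_cum)
        elif out_cum is not None:
            chrom, mid = _sample_mid(rng, complement, out_cum)
        else:
            chrom, mid = _sample_mid(rng, rois, roi_cum)
        chrom_len = cfg.chrom_lengths[chrom]
        start = int(np.clip(mid - size // 2, 0, chrom_len - size))
        intervals.append(GenomicInterval(chrom, start, start + size, f"{name}_{i:05d}"))
    return FeatureTrack(name, intervals)


def simulate_hic(truth: SyntheticTruth, resolution: int, cfg: SimConfig):
    """Sparse intra-chromosomal contact maps with planted loops.

    Background entries appear at bin distance *d* with probability
    ``min(1, hic_density/(1+d))`` and carry log-normal signal around the
    power-law mean ``hic_amp·(1+d)^(−hic_alpha)``; planted anchor pairs get
    ``hic_boost`` times the background mean at their distance, so they stand
    clear of the same-distance background quantiles.

    Returns a dict ``chrom -> HiCContactMap``.
    """
    from .hic import HiCContactMap, interval_to_bins

    if resolution <= 0:
        raise ValueError("resolution must be positive")
    rng = spawn_rng(cfg.seed, "hic", resolution)
    maps = {}
    for chrom, length in cfg.chrom_lengths.items():
        n_bins = (length + resolution - 1) // resolution
        entries: dict[tuple[int, int], float] = {}
        for i in range(n_bins):
            max_j = n_bins - i
            d = np.arange(max_j)
            keep = rng.random(max_j) < np.minimum(1.0, cfg.hic_density / (1.0 + d))
            for dj in d[keep]:
                mean = cfg.hic_amp * (1.0 + dj) ** (-cfg.hic_alpha)
                entries[(i, i + int(dj))] = mean * float(rng.lognormal(0.0, 0.5))
        maps[chrom] = HiCContactMap(resolution=resolution, chrom=chrom, entries=entries)
    for a, b, level in truth.hic_true_pairs:
        if a.chrom != b.chrom:
            raise ValueError("planted Hi-C pair must be intra-chromosomal")
        if a.chrom not in maps:
            raise ValueError(f"planted Hi-C anchor off-genome: {a.chrom}")
        length = cfg.chrom_lengths[a.chrom]
        if a.end > length or b.end > length:
            raise ValueError("planted Hi-C anchor off-chromosome")
        cmap = maps[a.chrom]
        bins_a = interval_to_bins(a, resolution)
        bins_b = interval_to_bins(b, resolution)
        for bi in bins_a:
            for bj in bins_b:
                lo, hi = min(bi, bj), max(bi, bj)
                d = hi - lo
                mean = cfg.hic_amp * (1.0 + d) ** (-cfg.hic_alpha)
                cmap.entries[(lo, hi)] = cfg.hic_boost * level * mean
    return maps


def truth_to_records(truth: SyntheticTruth) -> list[dict]:
    """Flatten the ledger for TSV/JSON export."""
    recs = [
        {"kind": "planted_pair", **asdict(p)} for p in truth.planted_pairs
    ]
    recs += [{"kind": "null_cpg", "phenotype_id": c} for c in truth.null_cpg_ids]
    recs += [{"kind": "ld_pair", **asdict(l)} for l in truth.ld_pairs]
    recs += [{"kind": "expression_effect", **asdict(e)} for e in truth.expression_effects]
    recs += [{"kind": "null_gene", "gene_id": g} for g in truth.null_gene_ids]
    return recs
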