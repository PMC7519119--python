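"""Hi-C contact lookup and the matched-pair permutation enrichment test.

CNV/CpG pairs are mapped onto binned, KR-normalized intra-chromosomal
contacts; the enrichment null re-draws, per chromosome, random CNV-like and
CpG-like regions with the observed length multisets and re-pairs them at the
observed midpoint distances, then counts how many random pairs land on a
non-zero contact entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import spawn_rng
from .types import GenomicInterval


@dataclass
class HiCContactMap:
    """Sparse upper-triangular bin-pair store of KR-normalized signal."""

    resolution: int
    chrom: str
    entries: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for (i, j), v in self.entries.items():
            if i > j:
                raise ValueError("entries must be stored with i <= j")
            if v < 0:
                raise ValueError("KR-normalized signal must be non-negative")

    def get(self, bin_i: int, bin_j: int) -> float:
        if bin_i > bin_j:
            bin_i, bin_j = bin_j, bin_i
        return self.entries.get((bin_i, bin_j), 0.0)


@dataclass(frozen=True)
class PairInteraction:
    """Contact signal for one CNV/CpG pair."""

    cnv_id: str
    cpg_id: str
    window_bp: int
    bin_pairs: tuple[tuple[int, int], ...]
    signal: float
    nonzero: bool


def interval_to_bins(iv: GenomicInterval, resolution: int) -> range:
    """Bins touched by a half-open interval: floor(start/res)..floor((end-1)/res)."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if iv.end <= iv.start:
        raise ValueError("empty interval")
    return range(iv.start // resolution, (iv.end - 1) // resolution + 1)


def pair_signal(
    cnv: GenomicInterval,
    cpg: GenomicInterval,
    window_bp: int,
    cmap: HiCContactMap,
) -> PairInteraction:
    """Maximum KR-normalized contact between a CNV and a ±window-extended CpG.

    The CpG is extended by ``window_bp`` on both sides (shore allowance) and
    the signal is the maximum over every (CNV bin, CpG bin) combination —
    which preserves the nonzero/zero statistic exactly.
    """
    if cnv.chrom != cpg.chrom:
        raise ValueError("pair signal is defined for intra-chromosomal pairs only")
    ext = GenomicInterval(cpg.chrom, max(0, cpg.start - window_bp), cpg.end + window_bp)
    best = 0.0
    pairs = []
    for bi in interval_to_bins(cnv, cmap.resolution):
        for bj in interval_to_bins(ext, cmap.resolution):
            lo, hi = min(bi, bj), max(bi, bj)
            pairs.append((lo, hi))
            v = cmap.get(lo, hi)
            if v > best:
                best = v
    return PairInteraction(
        cnv_id=cnv.id,
        cpg_id=cpg.id,
        window_bp=window_bp,
        bin_pairs=tuple(sorted(set(pairs))),
        signal=best,
        nonzero=best > 0,
    )


def sample_matched_pairs(
    pairs: list[tuple[GenomicInterval, GenomicInterval]],
    genome: dict[str, int],
    seed: int,
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """One permutation draw of size- and distance-matched random pairs.

    Per chromosome: CNV-role lengths, CpG-role lengths and midpoint-to-
    midpoint distances are each permuted within the chromosome's pairs and
    re-realized at uniform anchor positions (partner direction random,
    placements that fall off the chromosome are resampled).  The three
    multisets are preserved exactly.
    """
    by_chrom: dict[str, list[tuple[GenomicInterval, GenomicInterval]]] = {}
    for cnv, cpg in pairs:
        if cnv.chrom != cpg.chrom:
            raise ValueError("matched sampling is intra-chromosomal only")
        by_chrom.setdefault(cnv.chrom, []).append((cnv, cpg))
    rng = spawn_rng(seed, "matched-pairs")
    out = []
    for chrom in sorted(by_chrom):
        chrom_len = genome[chrom]
        group = by_chrom[chrom]
        k = len(group)
        cnv_lens = [c.length for c, _ in group]
        cpg_lens = [g.length for _, g in group]
        dists = [abs(c.midpoint - g.midpoint) for c, g in group]
        order_a = rng.permutation(k)
        order_b = rng.permutation(k)
        order_d = rng.permutation(k)
        for i in range(k):
            la, lb, d = cnv_lens[order_a[i]], cpg_lens[order_b[i]], dists[order_d[i]]
            if d + la // 2 + lb // 2 >= chrom_len:
                raise ValueError(f"matched distance {d} does not fit on {chrom}")
            for _ in range(10_000):
                a_mid = int(rng.integers(la // 2, chrom_len - (la - la // 2) + 1))
                b_mid = a_mid + (d if rng.random() < 0.5 else -d)
                if b_mid - lb // 2 < 0 or b_mid + (lb - lb // 2) > chrom_len:
                    continue
                a = GenomicInterval(chrom, a_mid - la // 2, a_mid - la // 2 + la)
                b = GenomicInterval(chrom, b_mid - lb // 2, b_mid - lb // 2 + lb)
                out.append((a, b))
                break
            else:
                raise RuntimeError(f"could not place matched pair on {chrom}")
    return out


def hic_permutation_test(
    pairs: list[tuple[GenomicInterval, GenomicInterval]],
    maps: dict[str, HiCContactMap],
    genome: dict[str, int],
    *,
    window_bp: int = 5000,
    iterations: int = 1000,
    seed: int = 0,
) -> dict:
    """Matched-null permutation test on the count of non-zero contact pairs.

    ``p_enrich = (1 + #{null >= observed}) / (iterations + 1)``;
    ``log_ratios[i] = log((observed + 1) / (null_i + 1))`` (add-one smoothing
    guards against zero null counts).
    """
    if not pairs:
        raise ValueError("empty pair set")
    if iterations < 100:
        raise ValueError("need at least 100 iterations")

    def count_nonzero(pair_set):
        total = 0
        for cnv, cpg in pair_set:
            cmap = maps.get(cnv.chrom)
            if cmap is None:
                continue
            if pair_signal(cnv, cpg, window_bp, cmap).nonzero:
                total += 1
        return total

    observed = count_nonzero(pairs)
    canonical = sorted(pairs, key=lambda p: (p[0].chrom, p[0].start, p[1].start, p[0].end))
    null_counts = np.array(
        [
            count_nonzero(sample_matched_pairs(canonical, genome, seed=int(spawn_rng(seed, "iter", i).integers(2**31))))
            for i in range(iterations)
        ]
    )
    p_enrich = (1.0 + int((null_counts >= observed).sum())) / (iterations + 1.0)
    log_ratios = np.log((observed + 1.0) / (null_counts + 1.0))
    return {
        "observed": observed,
        "null_counts": null_counts,
        "p_enrich": p_enrich,
        "log_ratios": log_ratios,
        "n_pairs": len(pairs),
    }
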