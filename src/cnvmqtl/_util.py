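"""Internal helpers: seeded RNG streams and fast interval arithmetic."""

from __future__ import annotations

import zlib

import numpy as np

from .types import GenomicInterval


def spawn_rng(seed: int, *keys) -> np.random.Generator:
    """A reproducible, order-independent RNG stream.

    Each (seed, keys...) combination gets its own counter-based stream via
    ``SeedSequence`` so sub-computations (one per phenotype, per generator,
    per iteration) can run in any order — or in parallel — and still
    reproduce bit-identically.  String keys are hashed with crc32 to keep the
    entropy pool integer-valued and stable across processes.
    """
    ints = [seed & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or touching-by-overlap intervals per chromosome.

    Half-open convention: abutting intervals ([0,5), [5,9)) are *not* merged
    unless they share at least one base.
    """
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


class MergedTrackIndex:
    """Per-chromosome sorted, merged interval arrays for batch overlap tests.

    Built once per track, then ``overlaps(chroms, starts, ends)`` answers
    "does each query share >=1 bp with the track" with two searchsorted
    calls per chromosome — the hot path inside permutation loops.
    """

    def __init__(self, intervals: list[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in merge_intervals(intervals):
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            starts = np.array([p[0] for p in pairs], dtype=np.int64)
            ends = np.array([p[1] for p in pairs], dtype=np.int64)
            self._chrom[chrom] = (starts, ends)

    def overlaps(self, chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean vector: query i shares >=1 bp with the merged track.

        Merged intervals are disjoint and sorted, so both starts and ends are
        increasing: the rightmost interval with start < query end carries the
        maximal end among all candidates, and a single comparison decides.
        """
        hit = np.zeros(len(starts), dtype=bool)
        chroms = np.asarray(chroms)
        for chrom, (tstarts, tends) in self._chrom.items():
            sel = chroms == chrom
            if not sel.any():
                continue
            qs = np.asarray(starts)[sel]
            qe = np.asarray(ends)[sel]
            idx = np.searchsorted(tstarts, qe, side="left") - 1
            ok = idx >= 0
            hit[sel] = ok & (tends[np.clip(idx, 0, None)] > qs)
        return hit
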