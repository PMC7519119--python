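"""Core genomic data containers.

All coordinates are 0-based, half-open (BED convention).  The midpoint of an
interval is ``floor((start + end) / 2)``; it is the anchor for the proximal /
distal window logic used throughout the QTL scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with a stable id."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start for {self.id or self.chrom}: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start for {self.id or self.chrom}: "
                f"[{self.start}, {self.end})"
            )
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap


def _check_unique_ids(intervals: Sequence[GenomicInterval], what: str) -> None:
    ids = [iv.id for iv in intervals]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")


@dataclass
class FeatureTrack:
    """A named set of genomic intervals (BED-style track)."""

    name: str
    intervals: list[GenomicInterval]

    def __post_init__(self):
        if not self.name:
            raise ValueError("track name must be non-empty")

    def __len__(self) -> int:
        return len(self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Chromosome": [iv.chrom for iv in self.intervals],
                "Start": [iv.start for iv in self.intervals],
                "End": [iv.end for iv in self.intervals],
                "Name": [iv.id for iv in self.intervals],
            }
        )


class _AnnotatedMatrix:
    """Shared behaviour for row-interval × sample matrices."""

    def __init__(
        self,
        rows: Sequence[GenomicInterval],
        samples: Sequence[str],
        values: np.ndarray,
        *,
        what: str,
    ):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(rows), len(samples)):
            raise ValueError(
                f"{what} matrix shape {values.shape} does not match "
                f"{len(rows)} rows × {len(samples)} samples"
            )
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        _check_unique_ids(rows, what)
        self.rows = list(rows)
        self.samples = list(samples)
        self.values = values
        self._index = {iv.id: i for i, iv in enumerate(self.rows)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def ids(self) -> list[str]:
        return [iv.id for iv in self.rows]

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self._index[row_id]]

    def interval(self, row_id: str) -> GenomicInterval:
        return self.rows[self._index[row_id]]

    def subset_rows(self, row_ids: Iterable[str]):
        idx = [self._index[r] for r in row_ids]
        return type(self)([self.rows[i] for i in idx], self.samples, self.values[idx])

    def subset_samples(self, sample_ids: Sequence[str]):
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return type(self)(self.rows, list(sample_ids), self.values[:, idx])


class GenotypeMatrix(_AnnotatedMatrix):
    """Integer copy-number states or allele dosages, variants × samples.

    Missing genotypes are stored as NaN and handled pairwise-complete
    downstream.  Non-missing entries must be non-negative integers.
    """

    def __init__(self, variants, samples, values):
        super().__init__(variants, samples, values, what="variant")
        vals = self.values
        present = ~np.isnan(vals)
        if np.any(vals[present] < 0):
            raise ValueError("genotype values must be non-negative")
        if not np.allclose(vals[present], np.round(vals[present])):
            raise ValueError("genotype values must be integers")

    @property
    def variants(self) -> list[GenomicInterval]:
        return self.rows

    @property
    def mask(self) -> np.ndarray:
        """True where the genotype is missing."""
        return np.isnan(self.values)

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency, folded into [0, 0.5].

        Copy-number states above 2 are recoded as diploid dosage of the
        non-reference allele, ``|state - 2|`` capped at 2.  Values already in
        0..2 are treated as allele counts directly; for the folded frequency
        the two readings coincide (the recoding swaps 0 and 2).
        """
        vals = self.values
        present = ~np.isnan(vals)
        out = np.empty(len(self.rows))
        for i in range(len(self.rows)):
            v = vals[i, present[i]]
            if v.max(initial=0) > 2:
                dosage = np.minimum(np.abs(v - 2), 2)
            else:
                dosage = v
            freq = dosage.sum() / (2 * len(dosage)) if len(dosage) else 0.0
            out[i] = min(freq, 1 - freq)
        return out


class MethylationMatrix(_AnnotatedMatrix):
    """CpG methylation β-values in [0, 1], sites × samples."""

    def __init__(self, sites, samples, beta):
        super().__init__(sites, samples, beta, what="site")
        if np.isnan(self.values).any():
            raise ValueError("missing β-values are not allowed")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("β-values must lie in [0, 1]")

    @property
    def sites(self) -> list[GenomicInterval]:
        return self.rows

    @property
    def beta(self) -> np.ndarray:
        return self.values


class ExpressionMatrix(_AnnotatedMatrix):
    """Non-negative expression estimates, genes × samples."""

    def __init__(self, genes, samples, expr):
        super().__init__(genes, samples, expr, what="gene")
        if np.isnan(self.values).any():
            raise ValueError("missing expression values are not allowed")
        if self.values.min() < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[GenomicInterval]:
        return self.rows

    @property
    def expr(self) -> np.ndarray:
        return self.values


@dataclass
class GeneModel:
    """A gene span with biotype and exon structure."""

    gene: GenomicInterval
    biotype: str
    exons: list[GenomicInterval] = field(default_factory=list)

    BIOTYPES = ("protein_coding", "lncRNA", "pseudogene")

    def __post_init__(self):
        if self.biotype not in self.BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        for ex in self.exons:
            if ex.chrom != self.gene.chrom or ex.start < self.gene.start or ex.end > self.gene.end:
                raise ValueError(f"exon {ex.id} outside gene span {self.gene.id}")


def align_samples(*matrices: _AnnotatedMatrix) -> list[_AnnotatedMatrix]:
    """Restrict matrices to their shared samples.

    Order is taken from the first matrix (conventionally the genotypes);
    unmatched samples are dropped with a warning on the module logger.
    """
    import logging

    shared = [s for s in matrices[0].samples if all(s in m.samples for m in matrices[1:])]
    if not shared:
        raise ValueError("no shared samples across matrices")
    dropped = sum(len(m.samples) - len(shared) for m in matrices)
    if dropped:
        logging.getLogger(__name__).warning(
            "sample alignment dropped %d non-shared sample columns", dropped
        )
    return [m.subset_samples(shared) for m in matrices]
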