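"""Readers and writers for the plain-text formats the pipeline touches.

* BED (3-4 column) for every interval set;
* a fixed TSV dialect for matrices: ``chrom  start  end  id  <sample...>``;
* association tables as TSV;
* genome files as two-column ``chrom  length`` TSV;
* sparse Hi-C contacts as ``bin_i_start  bin_j_start  value`` TSV per
  chromosome (a 7-column juicer-style dump reader is provided as a
  convenience);
* gene models as a BED12-like TSV with biotype and exon blocks.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .association import AssociationRecord
from .types import (
    ExpressionMatrix,
    FeatureTrack,
    GeneModel,
    GenomicInterval,
    GenotypeMatrix,
    MethylationMatrix,
)

_MATRIX_KINDS = {
    "genotype": GenotypeMatrix,
    "methylation": MethylationMatrix,
    "expression": ExpressionMatrix,
}

ASSOC_COLUMNS = ["variant_id", "phenotype_id", "mode", "distance", "rho", "nominal_p", "perm_p"]


class ParseError(ValueError):
    pass


def read_bed(path, name: str | None = None) -> FeatureTrack:
    """Parse a 3+ column BED file into a :class:`FeatureTrack`.

    Coordinates are 0-based half-open.  A 4th column supplies the interval
    id; otherwise ids are auto-generated as ``chrom:start-end``.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                iv = GenomicInterval(fields[0], start, end, fields[3] if len(fields) > 3 else "")
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    return FeatureTrack(name or os.path.splitext(os.path.basename(path))[0], intervals)


def write_bed(track: FeatureTrack, path) -> None:
    with open(path, "w") as fh:
        for iv in track.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")


def _intervals_from_frame(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(str(c), int(s), int(e), str(i))
        for c, s, e, i in zip(df["chrom"], df["start"], df["end"], df["id"])
    ]


def read_matrix(path, kind: str):
    """Read a matrix TSV (``chrom start end id`` + one column per sample).

    ``NA`` cells are allowed for ``kind="genotype"`` (they enter the missing
    mask) and rejected for methylation/expression.
    """
    if kind not in _MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "start", "end", "id"]
    if list(df.columns[:4]) != required:
        raise ParseError(f"{path}: first columns must be {required}")
    samples = list(df.columns[4:])
    if not samples:
        raise ParseError(f"{path}: no sample columns")
    values = df[samples].to_numpy(dtype=float)
    if kind != "genotype" and np.isnan(values).any():
        raise ValueError(f"{path}: NA values not allowed in {kind} matrices")
    return _MATRIX_KINDS[kind](_intervals_from_frame(df), samples, values)


def write_matrix(matrix, path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in matrix.rows],
            "start": [iv.start for iv in matrix.rows],
            "end": [iv.end for iv in matrix.rows],
            "id": [iv.id for iv in matrix.rows],
        }
    )
    vals = matrix.values
    if isinstance(matrix, GenotypeMatrix):
        body = pd.DataFrame(vals, columns=matrix.samples).astype(object)
        for col in body.columns:
            body[col] = [("NA" if np.isnan(v) else int(v)) for v in body[col]]
    else:
        body = pd.DataFrame(np.round(vals, 10), columns=matrix.samples)
    pd.concat([df, body], axis=1).to_csv(path, sep="\t", index=False)


def write_associations(records: Iterable[AssociationRecord], path) -> None:
    """Write association records as TSV, sorted by (phenotype_id, perm_p)."""
    rows = [
        (r.variant_id, r.phenotype_id, r.mode, r.distance, r.rho, r.nominal_p, r.perm_p)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=ASSOC_COLUMNS)
    df = df.sort_values(
        ["phenotype_id", "perm_p", "variant_id", "mode"], kind="mergesort"
    ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_associations(path) -> list[AssociationRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        AssociationRecord(
            variant_id=str(r.variant_id),
            phenotype_id=str(r.phenotype_id),
            rho=float(r.rho),
            nominal_p=float(r.nominal_p),
            perm_p=float(r.perm_p),
            mode=str(r.mode),
            distance=int(r.distance),
        )
        for r in df.itertuples()
    ]


def read_genome(path) -> dict[str, int]:
    """Two-column ``chrom<TAB>length`` file -> ordered dict of lengths."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected chrom and length")
            genome[fields[0]] = int(fields[1])
    return genome


def write_genome(genome: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


def read_contacts(path, resolution: int, chrom: str):
    """Read a sparse 3-column contact TSV into a :class:`HiCContactMap`.

    Columns: ``bin_i_start  bin_j_start  kr_normalized_value`` (bp starts of
    the two bins, as in a juicer short dump for one chromosome).
    """
    from .hic import HiCContactMap

    entries: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 7:  # juicer-style: str1 chr1 pos1 str2 chr2 pos2 score
                pos_i, pos_j, val = int(fields[2]), int(fields[5]), float(fields[6])
            elif len(fields) >= 3:
                pos_i, pos_j, val = int(fields[0]), int(fields[1]), float(fields[2])
            else:
                raise ParseError(f"{path}:{lineno}: expected 3 or 7 columns")
            bi, bj = pos_i // resolution, pos_j // resolution
            if bi > bj:
                bi, bj = bj, bi
            entries[(bi, bj)] = val
    return HiCContactMap(resolution=resolution, chrom=chrom, entries=entries)


def write_contacts(cmap, path) -> None:
    with open(path, "w") as fh:
        for (bi, bj), val in sorted(cmap.entries.items()):
            fh.write(f"{bi * cmap.resolution}\t{bj * cmap.resolution}\t{val:.6g}\n")


def read_gene_models(path) -> list[GeneModel]:
    """BED12-like gene model TSV.

    Columns: chrom, start, end, gene_id, biotype, exon_starts, exon_sizes
    (the last two comma-separated, relative to the gene start; may be empty).
    """
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected >=5 columns")
            chrom, start, end, gid, biotype = fields[:5]
            gene = GenomicInterval(chrom, int(start), int(end), gid)
            exons = []
            if len(fields) >= 7 and fields[5]:
                starts = [int(x) for x in fields[5].rstrip(",").split(",")]
                sizes = [int(x) for x in fields[6].rstrip(",").split(",")]
                if len(starts) != len(sizes):
                    raise ParseError(f"{path}:{lineno}: exon starts/sizes mismatch")
                exons = [
                    GenomicInterval(chrom, gene.start + s, gene.start + s + z, f"{gid}.exon{k}")
                    for k, (s, z) in enumerate(zip(starts, sizes), start=1)
                ]
            models.append(GeneModel(gene=gene, biotype=biotype, exons=exons))
    return models
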