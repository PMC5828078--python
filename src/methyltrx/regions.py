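"""Promoter, exon and gene-body windows, and positional count aggregation.

The promoter window spans 5000 bp upstream and 200 bp downstream of the
transcription start site by default, strand-aware; the TSS base itself
belongs to the downstream side.  Region ids follow ``geneId|kind`` with
kind in {promoter, exon, body}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CountMatrix, GeneAnnotation, GenomicInterval, ValidationError

logger = logging.getLogger(__name__)

REGION_KINDS = ("promoter", "exon", "body")


@dataclass(frozen=True)
class Region:
    """One named region: a union of disjoint intervals belonging to one gene."""

    region_id: str
    kind: str
    gene_id: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValidationError(f"unknown region kind {self.kind!r}")
        if self.kind == "promoter" and len(self.intervals) != 1:
            raise ValidationError("promoter region must be a single interval")
        if not self.intervals:
            raise ValidationError(f"region {self.region_id} has no intervals")

    def contains(self, pos: int) -> bool:
        return any(iv.contains(pos) for iv in self.intervals)


def region_id_for(gene_id: str, kind: str) -> str:
    return f"{gene_id}|{kind}"


def parse_region_id(region_id: str) -> tuple[str, str]:
    """Split ``geneId|kind``; the gene id may itself contain no pipe."""
    if region_id.count("|") != 1:
        raise ValidationError(f"region id {region_id!r} not of the form gene|kind")
    gene_id, kind = region_id.split("|")
    if kind not in REGION_KINDS:
        raise ValidationError(f"region id {region_id!r} has unknown kind {kind!r}")
    return gene_id, kind


def promoter_window(gene: GeneAnnotation, upstream: int = 5000,
                    downstream: int = 200,
                    chrom_length: int | None = None) -> GenomicInterval:
    """Strand-aware promoter interval around the TSS, clipped to the chromosome.

    On the plus strand the window is ``[tss - upstream, tss + downstream)``;
    the minus-strand window mirrors it around the TSS base.  The width is
    ``upstream + downstream`` except where clipping intervenes.
    """
    if upstream < 0 or downstream < 0:
        raise ValidationError("upstream and downstream must be non-negative")
    if upstream == 0 and downstream == 0:
        raise ValidationError("promoter window cannot be empty")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream + 1, gene.tss + upstream + 1
    clipped_start = max(start, 0)
    clipped_end = end if chrom_length is None else min(end, chrom_length)
    if clipped_start >= clipped_end:
        raise ValidationError(
            f"promoter window for {gene.gene_id} lies entirely outside the chromosome"
        )
    return GenomicInterval(gene.chrom, clipped_start, clipped_end, gene.strand)


def gene_region_set(genes: list[GeneAnnotation], upstream: int = 5000,
                    downstream: int = 200,
                    chrom_length: int | None = None) -> list[Region]:
    """One promoter, one merged-exon and one gene-body region per gene.

    Genes without exons get no exon region (a warning is logged).
    """
    regions: list[Region] = []
    for gene in genes:
        promoter = promoter_window(gene, upstream, downstream, chrom_length)
        regions.append(Region(region_id_for(gene.gene_id, "promoter"),
                              "promoter", gene.gene_id, (promoter,)))
        if gene.exons:
            regions.append(Region(region_id_for(gene.gene_id, "exon"),
                                  "exon", gene.gene_id, tuple(gene.exons)))
        else:
            logger.warning("gene %s has no exons; exon region omitted", gene.gene_id)
        regions.append(Region(region_id_for(gene.gene_id, "body"),
                              "body", gene.gene_id, (gene.body,)))
    seen: set[str] = set()
    for region in regions:
        if region.region_id in seen:
            raise ValidationError(f"duplicate region id {region.region_id}")
        seen.add(region.region_id)
    return regions


def count_positions_in_regions(positions: dict[str, np.ndarray | list[int]],
                               regions: list[Region],
                               groups: dict[str, str]) -> CountMatrix:
    """Aggregate per-sample base positions (e.g. read start coordinates) into
    region counts.

    A position contributes to every region whose interval union contains it.
    Intervals within one region are disjoint by construction, so per region
    the count is the sum of per-interval hits, computed by binary search on
    the sorted position vector.
    """
    region_ids = [r.region_id for r in regions]
    samples = list(positions)
    mat = np.zeros((len(regions), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        pos = np.sort(np.asarray(positions[sample], dtype=np.int64))
        for i, region in enumerate(regions):
            hits = 0
            for iv in region.intervals:
                hits += int(np.searchsorted(pos, iv.end, side="left")
                            - np.searchsorted(pos, iv.start, side="left"))
            mat[i, j] = hits
    counts = pd.DataFrame(mat, index=region_ids, columns=samples)
    return CountMatrix(counts, {s: groups[s] for s in samples})


def write_regions_bed(regions: list[Region], path: str | Path) -> None:
    """Export regions as BED6 lines (one line per interval, region_id in name)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for region in regions:
            for iv in region.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{region.region_id}\t0\t{iv.strand}\n")
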