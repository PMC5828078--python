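"""Shared domain types for the methylation/transcriptomics integration pipeline.

All genomic coordinates are 0-based half-open ``[start, end)``.  External
formats with other conventions (GTF is 1-based inclusive) are converted on
ingress and egress by :mod:`methyltrx.io`.

Count matrices are kept as raw non-negative integers; every normalization
happens downstream in :mod:`methyltrx.diffstats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STRANDS = {"+", "-", "."}
GROUP_CASE = "case"
GROUP_CONTROL = "control"
VALID_GROUPS = {GROUP_CASE, GROUP_CONTROL}


class ValidationError(ValueError):
    """An input violates a domain-type invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware half-open genomic interval.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive, so the width
    is simply ``end - start``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Half-open membership: start is in, end is out."""
        return self.start <= pos < self.end


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Sort intervals and merge overlapping or bookended ones.

    All intervals must share one chromosome; strand is taken from the first.
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValidationError(f"cannot merge intervals across chromosomes {chroms}")
    strand = intervals[0].strand
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[tuple[int, int]] = [(ordered[0].start, ordered[0].end)]
    for iv in ordered[1:]:
        last_start, last_end = merged[-1]
        if iv.start <= last_end:  # overlap or adjacency
            merged[-1] = (last_start, max(last_end, iv.end))
        else:
            merged.append((iv.start, iv.end))
    chrom = ordered[0].chrom
    return [GenomicInterval(chrom, s, e, strand) for s, e in merged]


@dataclass
class GeneAnnotation:
    """One gene: its TSS, strand, merged exons and annotated body span.

    The TSS sits at ``body.start`` on the plus strand and at ``body.end - 1``
    on the minus strand.  Exons are merged on construction so they are
    non-overlapping and sorted.
    """

    gene_id: str
    tss: int
    strand: str
    exons: list[GenomicInterval]
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        expected_tss = self.body.start if self.strand == "+" else self.body.end - 1
        if self.tss != expected_tss:
            raise ValidationError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with "
                f"body {self.body.start}-{self.body.end} on strand {self.strand}"
            )
        self.exons = merge_intervals(self.exons)
        for exon in self.exons:
            if exon.start < self.body.start or exon.end > self.body.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon [{exon.start}, {exon.end}) "
                    f"outside body [{self.body.start}, {self.body.end})"
                )

    @property
    def chrom(self) -> str:
        return self.body.chrom


class CountMatrix:
    """Features x samples raw integer counts with a two-level group factor.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, rows = feature ids (unique),
        columns = sample ids (unique).
    groups
        Mapping sample id -> ``"case"`` or ``"control"`` covering every
        sample in ``counts``.
    """

    def __init__(self, counts: pd.DataFrame, groups: dict[str, str] | pd.Series):
        counts = counts.copy()
        if counts.index.has_duplicates:
            raise ValidationError("duplicate feature ids in count matrix")
        if counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count matrix")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
        missing = [s for s in counts.columns if s not in groups.index]
        if missing:
            raise ValidationError(f"samples missing from groups: {missing}")
        groups = groups.loc[counts.columns]
        bad = sorted(set(groups) - VALID_GROUPS)
        if bad:
            raise ValidationError(
                f"group labels must be in {sorted(VALID_GROUPS)}, got {bad}"
            )
        self.counts = counts
        self.groups = groups

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def require_min_group_size(self, n: int) -> None:
        for group in sorted(VALID_GROUPS):
            k = int((self.groups == group).sum())
            if k < n:
                raise ValidationError(
                    f"group {group!r} has {k} samples; at least {n} required"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.groups.equals(other.groups)

    def __repr__(self) -> str:
        n_f, n_s = self.counts.shape
        return f"CountMatrix({n_f} features x {n_s} samples)"


# Differential test results travel between stages as a DataFrame with this
# column contract (one row per feature, feature_id unique).
DIFF_COLUMNS = ["feature_id", "mean_count", "log2fc", "pvalue", "qvalue"]


def validate_diff_result(df: pd.DataFrame) -> pd.DataFrame:
    """Check the DiffResult column contract and return the frame unchanged."""
    missing = [c for c in DIFF_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"diff result missing columns: {missing}")
    if df["feature_id"].duplicated().any():
        raise ValidationError("duplicate feature ids in diff result")
    for col in ("pvalue", "qvalue"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError(f"{col} outside [0, 1]")
    return df


@dataclass
class RegulatoryNetwork:
    """Directed TF -> target edges with parallel duplicates collapsed.

    ``graph`` is a :class:`networkx.DiGraph`; transcription factors are the
    nodes with out-degree >= 1.  Self-loops are retained but recorded in
    ``self_loops``.
    """

    graph: "object"
    self_loops: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def tfs(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.graph.out_degree(n) >= 1)

    def targets_of(self, tf: str) -> list[str]:
        if tf not in self.graph:
            raise ValidationError(f"{tf!r} not present in network")
        return sorted(self.graph.successors(tf))


class CompoundSignatureSet:
    """Replicated compound perturbation signatures over a shared gene universe.

    ``scores[(compound, context)]`` is an array of shape
    ``(n_genes, n_replicates)`` of differential-expression scores aligned to
    ``genes``.
    """

    def __init__(self, genes: pd.Index | list[str],
                 scores: dict[tuple[str, str], np.ndarray]):
        self.genes = pd.Index(genes)
        if self.genes.has_duplicates:
            raise ValidationError("duplicate genes in signature universe")
        self.scores: dict[tuple[str, str], np.ndarray] = {}
        for key, arr in scores.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None]
            if arr.shape[0] != len(self.genes):
                raise ValidationError(
                    f"signature {key} has {arr.shape[0]} genes, expected {len(self.genes)}"
                )
            if arr.shape[1] < 1:
                raise ValidationError(f"signature {key} has no replicates")
            self.scores[key] = arr

    @property
    def contexts(self) -> list[str]:
        return sorted({ctx for _, ctx in self.scores})

    @property
    def compounds(self) -> list[str]:
        return sorted({cpd for cpd, _ in self.scores})

    def n_genes(self) -> int:
        return len(self.genes)
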