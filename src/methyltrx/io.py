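"""Readers and writers for every external format the pipeline touches.

Formats: GTF (Ensembl dialect, converted 1-based inclusive <-> 0-based
half-open), BED12, GMT gene sets, RNK ranked lists, TSV count matrices and
group files, TSV/SIF edge lists, and per-(context, replicate) compound
signature tables.  All writers emit UTF-8, LF line endings, tab-separated
columns, and a deterministic row order (sorted by feature id unless an
explicit order is supplied).
"""

from __future__ import annotations

import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import (
    CompoundSignatureSet,
    CountMatrix,
    GeneAnnotation,
    GenomicInterval,
    RegulatoryNetwork,
    ValidationError,
)


class ParseError(ValueError):
    """A file does not parse under its named standard."""


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(attr_field))


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read gene models from GTF or BED12, dispatching on file extension.

    Returns genes with 0-based half-open coordinates, the TSS taken from the
    3'-most base of the annotated span on the minus strand, and overlapping
    exons merged.  Duplicate gene ids are rejected.
    """
    path = Path(path)
    if path.suffix.lower() in {".bed", ".bed12"}:
        return _read_bed12(path)
    return _read_gtf(path)


def _read_gtf(path: Path) -> list[GeneAnnotation]:
    bodies: dict[str, tuple[str, int, int, str]] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path}:{lineno}: invalid 1-based span {start1}..{end1}")
            if strand not in {"+", "-"}:
                raise ParseError(f"{path}:{lineno}: strand must be + or - for gene models")
            gene_id = _parse_gtf_attributes(attrs).get("gene_id")
            if not gene_id:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            # GTF is 1-based inclusive; internal coordinates 0-based half-open.
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if feature == "gene":
                if gene_id in bodies:
                    raise ValidationError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
                bodies[gene_id] = (chrom, iv.start, iv.end, strand)
                order.append(gene_id)
            elif feature == "exon":
                exons.setdefault(gene_id, []).append(iv)
    genes = []
    for gene_id in order:
        chrom, start, end, strand = bodies[gene_id]
        body = GenomicInterval(chrom, start, end, strand)
        tss = body.start if strand == "+" else body.end - 1
        genes.append(GeneAnnotation(gene_id, tss, strand, exons.get(gene_id, []), body))
    return genes


def _read_bed12(path: Path) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 fields, got {len(fields)}")
            chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
            strand = fields[5]
            try:
                start, end = int(start_s), int(end_s)
                block_count = int(fields[9])
                block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer BED12 field") from exc
            if strand not in {"+", "-"}:
                raise ParseError(f"{path}:{lineno}: strand must be + or -")
            if len(block_sizes) != block_count or len(block_starts) != block_count:
                raise ParseError(f"{path}:{lineno}: block count mismatch")
            if name in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {name!r}")
            seen.add(name)
            body = GenomicInterval(chrom, start, end, strand)
            exons = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(block_starts, block_sizes)
            ]
            tss = body.start if strand == "+" else body.end - 1
            genes.append(GeneAnnotation(name, tss, strand, exons, body))
    return genes


def write_gene_annotation_gtf(genes: list[GeneAnnotation], path: str | Path) -> None:
    """Write gene and exon features; internal 0-based half-open -> GTF 1-based."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene in genes:
            attrs = f'gene_id "{gene.gene_id}";'
            body = gene.body
            fh.write(
                f"{body.chrom}\tmethyltrx\tgene\t{body.start + 1}\t{body.end}\t."
                f"\t{gene.strand}\t.\t{attrs}\n"
            )
            for exon in gene.exons:
                fh.write(
                    f"{exon.chrom}\tmethyltrx\texon\t{exon.start + 1}\t{exon.end}\t."
                    f"\t{gene.strand}\t.\t{attrs}\n"
                )


def read_count_matrix(path: str | Path, groups_path: str | Path) -> CountMatrix:
    """Read a TSV count matrix (first column feature ids, header sample ids)
    together with a two-column sample -> group file."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.integer):
        raise ValidationError(f"{path}: counts must be integers")
    groups = read_groups(groups_path)
    missing = [s for s in df.columns if s not in groups]
    if missing:
        raise ValidationError(f"{groups_path}: samples missing from groups: {missing}")
    return CountMatrix(df, {s: groups[s] for s in df.columns})


def write_count_matrix(matrix: CountMatrix, path: str | Path,
                       groups_path: str | Path | None = None) -> None:
    df = matrix.counts
    df.to_csv(path, sep="\t", index_label="feature_id", lineterminator="\n")
    if groups_path is not None:
        write_groups(dict(matrix.groups), groups_path)


def read_groups(path: str | Path) -> dict[str, str]:
    groups: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected sample<TAB>group")
            if fields[0] == "sample" and fields[1] == "group":
                continue  # optional header
            groups[fields[0]] = fields[1]
    return groups


def write_groups(groups: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read named gene sets; duplicate members within a set count once."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name, _description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = set(members)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sorted(sets):
            members = sorted(sets[name])
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_rnk(path: str | Path) -> pd.Series:
    """Two-column gene<TAB>score ranked-list file -> Series ordered as on disk."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"], comment="#")
    if df["gene"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids in RNK file")
    return pd.Series(df["score"].to_numpy(float), index=df["gene"])


def write_rnk(scores: pd.Series, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene, score in scores.items():
            fh.write(f"{gene}\t{score:.10g}\n")


def read_network(path: str | Path) -> RegulatoryNetwork:
    """Read a directed edge list from two-column TSV or SIF.

    SIF rows are ``source<TAB>interaction<TAB>target [target2 ...]``; TSV
    rows are ``source<TAB>target``.  Parallel duplicate edges collapse to
    one; self-loops are retained and reported in ``self_loops``.
    """
    path = Path(path)
    is_sif = path.suffix.lower() == ".sif"
    graph = nx.DiGraph()
    self_loops: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if is_sif:
                if len(fields) < 3 or not fields[0] or not all(fields[2:]):
                    raise ParseError(f"{path}:{lineno}: malformed SIF row")
                source, targets = fields[0], fields[2:]
            else:
                if len(fields) != 2 or not fields[0] or not fields[1]:
                    raise ParseError(f"{path}:{lineno}: expected source<TAB>target")
                if fields == ["source", "target"]:
                    continue  # optional header
                source, targets = fields[0], [fields[1]]
            for target in targets:
                if source == target:
                    self_loops.add(source)
                graph.add_edge(source, target)
    return RegulatoryNetwork(graph=graph, self_loops=sorted(self_loops))


def write_network(network: RegulatoryNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttarget\n")
        for source, target in sorted(network.graph.edges):
            fh.write(f"{source}\t{target}\n")


def write_diff_result(df: pd.DataFrame, path: str | Path) -> None:
    """Differential-test output TSV (feature_id, baseMean, log2FC, pvalue, FDR)."""
    out = df.rename(
        columns={"mean_count": "baseMean", "log2fc": "log2FC", "qvalue": "FDR"}
    )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def read_diff_result(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(
        columns={"baseMean": "mean_count", "log2FC": "log2fc", "FDR": "qvalue"}
    )


def read_signature_dir(directory: str | Path) -> CompoundSignatureSet:
    """Assemble a :class:`CompoundSignatureSet` from one TSV per
    ``<context>_<replicate>.tsv`` (rows genes, columns compounds)."""
    directory = Path(directory)
    files = sorted(directory.glob("*.tsv"))
    if not files:
        raise ParseError(f"no signature TSV files under {directory}")
    genes: pd.Index | None = None
    per_key: dict[tuple[str, str], list[np.ndarray]] = {}
    for f in files:
        stem = f.stem
        if "_" not in stem:
            raise ParseError(f"{f}: expected file name <context>_<replicate>.tsv")
        context, _rep = stem.rsplit("_", 1)
        df = pd.read_csv(f, sep="\t", index_col=0)
        if genes is None:
            genes = df.index
        elif not genes.equals(df.index):
            raise ValidationError(f"{f}: gene universe differs between signature files")
        for compound in df.columns:
            per_key.setdefault((compound, context), []).append(df[compound].to_numpy(float))
    assert genes is not None
    scores = {key: np.column_stack(reps) for key, reps in per_key.items()}
    return CompoundSignatureSet(genes, scores)


def write_signature_dir(signatures: CompoundSignatureSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    per_file: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for (compound, context), arr in signatures.scores.items():
        for rep in range(arr.shape[1]):
            per_file.setdefault((context, rep), {})[compound] = arr[:, rep]
    for (context, rep), columns in sorted(per_file.items()):
        df = pd.DataFrame(
            {cpd: columns[cpd] for cpd in sorted(columns)}, index=signatures.genes
        )
        df.to_csv(
            directory / f"{context}_{rep + 1}.tsv",
            sep="\t", index_label="gene", lineterminator="\n", float_format="%.10g",
        )
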