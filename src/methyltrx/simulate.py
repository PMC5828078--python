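"""Synthetic datasets with planted, recoverable structure.

The generator emulates the statistical design of the study this pipeline
serves: two groups of five animals, negative-binomial feature counts for
both the expression and methylation arms, a minority of genes with planted
log2 fold-changes, promoter hypermethylation that can be anti-coupled to
expression (hypermethylated promoter => downregulated gene), a directed
TF->target network in which a stated fraction of each planted regulon is
dysregulated, and replicated compound signatures over three neural cell
contexts with a few planted hit compounds.

Everything is bit-reproducible given (config, seed): each generator stage
draws from its own stream ``default_rng([seed, stage_code])`` so stages are
independent of call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    CompoundSignatureSet,
    CountMatrix,
    GeneAnnotation,
    GenomicInterval,
    RegulatoryNetwork,
    ValidationError,
)
from . import io as mio
from .regions import gene_region_set

# Stage codes for per-stage random streams.
_STAGE_TRUTH = 0
_STAGE_ANNOTATION = 1
_STAGE_EXPRESSION = 2
_STAGE_METHYLATION = 3
_STAGE_SIGNATURES = 5

_TSS_SPACING = 15_000  # guarantees promoter windows (+-5200 bp) never collide
_FIRST_TSS = 10_000


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults mirror the emulated design."""

    n_genes: int = 2000
    n_case: int = 5
    n_control: int = 5
    seed: int = 0
    nb_dispersion: float = 0.1
    baseline_mean_expr: float = 200.0
    baseline_mean_meth: float = 100.0
    library_size_factors: list[float] | None = None
    frac_de: float = 0.1
    lfc_de: float = 1.5
    frac_dm_promoter: float = 0.05
    lfc_dm: float = 1.5
    coupling: str = "anti"  # "anti" or "none"
    n_tfs: int = 4
    regulon_size: int = 50
    frac_regulon_altered: float = 0.3
    tf_lfc: float = 1.5
    n_background_tfs: int = 8
    frac_regulon_altered_bg: float = 0.02
    n_compounds: int = 200
    cell_contexts: list[str] = field(default_factory=lambda: ["NEU", "NEU.KCL", "NPC"])
    n_replicates_per_signature: int = 3
    compound_effect_size: float = 10.0
    n_hit_compounds: int = 5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("frac_de", "frac_dm_promoter", "frac_regulon_altered",
                     "frac_regulon_altered_bg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_genes", "n_case", "n_control", "n_tfs", "regulon_size",
                     "n_compounds", "n_replicates_per_signature"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.coupling not in {"anti", "none"}:
            raise ValidationError("coupling must be 'anti' or 'none'")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        n_dm = round(self.frac_dm_promoter * self.n_genes)
        n_de = round(self.frac_de * self.n_genes)
        if self.coupling == "anti" and n_dm > n_de:
            raise ValidationError(
                "coupling='anti' requires frac_dm_promoter <= frac_de "
                "(every hypermethylated promoter must map to a downregulated gene)"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """The planted structure, the oracle every downstream test recovers."""

    de_genes: dict[str, float]            # gene -> true expression log2FC
    dm_promoters: dict[str, float]        # gene -> true promoter methylation log2FC
    coupled_pairs: list[str]              # genes both hypermethylated and down
    tf_regulons: dict[str, list[str]]     # TF -> regulon members
    tf_altered: dict[str, dict[str, float]]  # TF -> altered targets with lfc
    tf_lfc: dict[str, float]              # planted TF expression log2FC
    background_tfs: list[str]
    compound_hits: list[dict]             # {compound, tf, direction, context}


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stage])


def _gene_ids(config: SimulationConfig) -> list[str]:
    width = max(4, len(str(config.n_genes - 1)))
    return [f"g{i:0{width}d}" for i in range(config.n_genes)]


def plan_truth(config: SimulationConfig) -> SyntheticTruth:
    """Assign every planted effect before any counts are drawn.

    The differential-expression budget ``round(frac_de * n_genes)`` covers,
    in order, the anti-coupled hypermethylated genes, the planted TFs, the
    altered regulon targets, and finally free DE genes; all categories are
    disjoint so truth sets stay unambiguous.
    """
    rng = _rng(config, _STAGE_TRUTH)
    genes = _gene_ids(config)
    n_de = round(config.frac_de * config.n_genes)
    n_dm = round(config.frac_dm_promoter * config.n_genes)

    n_tf_total = config.n_tfs + config.n_background_tfs
    need = n_tf_total * (1 + config.regulon_size)
    if need > config.n_genes:
        raise ValidationError(
            f"n_genes={config.n_genes} too small for {n_tf_total} TFs with "
            f"regulon size {config.regulon_size}"
        )
    shuffled = list(rng.permutation(genes))
    tf_ids = shuffled[:n_tf_total]
    planted_tfs = tf_ids[: config.n_tfs]
    background_tfs = tf_ids[config.n_tfs:]
    cursor = n_tf_total
    tf_regulons: dict[str, list[str]] = {}
    for tf in tf_ids:
        tf_regulons[tf] = sorted(shuffled[cursor: cursor + config.regulon_size])
        cursor += config.regulon_size

    tf_altered: dict[str, dict[str, float]] = {}
    for tf in tf_ids:
        frac = (config.frac_regulon_altered if tf in planted_tfs
                else config.frac_regulon_altered_bg)
        k = round(frac * config.regulon_size)
        chosen = list(rng.choice(tf_regulons[tf], size=k, replace=False)) if k else []
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        tf_altered[tf] = {g: s * abs(config.lfc_de) for g, s in zip(sorted(chosen), signs)}

    tf_lfc = {tf: float(rng.choice([-1.0, 1.0])) * abs(config.tf_lfc)
              for tf in planted_tfs}

    network_genes = set(tf_ids) | {g for r in tf_regulons.values() for g in r}
    free_pool = [g for g in shuffled[cursor:] if g not in network_genes]

    dm_candidates = free_pool  # disjoint from the network so regulon truth stays exact
    if n_dm > len(dm_candidates):
        raise ValidationError("not enough genes outside the network for dm_promoters")
    dm_genes = sorted(dm_candidates[:n_dm])
    dm_promoters = {g: abs(config.lfc_dm) for g in dm_genes}

    de_genes: dict[str, float] = {}
    coupled: list[str] = []
    if config.coupling == "anti":
        for g in dm_genes:
            de_genes[g] = -abs(config.lfc_de)
        coupled = list(dm_genes)
    for tf, lfc in tf_lfc.items():
        if lfc != 0.0:
            de_genes[tf] = lfc
    for tf in tf_ids:
        de_genes.update({g: v for g, v in tf_altered[tf].items() if v != 0.0})

    remaining = [g for g in free_pool[n_dm:] if g not in de_genes]
    n_free = n_de - len(de_genes)
    if n_free < 0:
        raise ValidationError(
            "frac_de budget too small to hold coupled genes, TFs and altered targets"
        )
    if n_free > len(remaining):
        raise ValidationError("not enough genes left for free DE genes")
    free_signs = rng.choice([-1.0, 1.0], size=n_free)
    for g, s in zip(remaining[:n_free], free_signs):
        de_genes[g] = float(s) * abs(config.lfc_de)

    return SyntheticTruth(
        de_genes=de_genes,
        dm_promoters=dm_promoters,
        coupled_pairs=coupled,
        tf_regulons=tf_regulons,
        tf_altered=tf_altered,
        tf_lfc=tf_lfc,
        background_tfs=background_tfs,
        compound_hits=_plan_compound_hits(config, planted_tfs),
    )


def _plan_compound_hits(config: SimulationConfig, planted_tfs: list[str]) -> list[dict]:
    hits = []
    for i in range(min(config.n_hit_compounds, config.n_compounds)):
        hits.append({
            "compound": f"cpd{i:04d}",
            "tf": planted_tfs[i % len(planted_tfs)],
            "direction": "up" if i % 2 == 0 else "down",
            "context": config.cell_contexts[i % len(config.cell_contexts)],
        })
    return hits


def simulate_annotation(config: SimulationConfig) -> list[GeneAnnotation]:
    """Genes tiled on one synthetic chromosome, TSSs on a 15 kb grid
    (promoter windows can never collide), alternating strands, 1-5 exons."""
    rng = _rng(config, _STAGE_ANNOTATION)
    genes = []
    for i, gene_id in enumerate(_gene_ids(config)):
        tss = _FIRST_TSS + i * _TSS_SPACING
        strand = "+" if i % 2 == 0 else "-"
        length = int(rng.integers(2000, 8001))
        if strand == "+":
            body = GenomicInterval("chrS", tss, tss + length, strand)
        else:
            body = GenomicInterval("chrS", tss - length + 1, tss + 1, strand)
        n_exons = int(rng.integers(1, 6))
        w = max(1, length // (2 * n_exons))
        exons = []
        for k in range(n_exons):
            start = body.start + k * 2 * w
            end = min(start + w, body.end)
            if start < end:
                exons.append(GenomicInterval("chrS", start, end, strand))
        genes.append(GeneAnnotation(gene_id, tss, strand, exons, body))
    return genes


def _library_factors(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_case + config.n_control
    if config.library_size_factors is not None:
        factors = np.asarray(config.library_size_factors, dtype=float)
        if factors.size != n:
            raise ValidationError("library_size_factors length must equal sample count")
        return factors
    return 2.0 ** rng.uniform(-0.25, 0.25, size=n)


def _sample_names_groups(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    cases = [f"tbi_{i + 1}" for i in range(config.n_case)]
    controls = [f"sham_{i + 1}" for i in range(config.n_control)]
    groups = {s: "case" for s in cases} | {s: "control" for s in controls}
    return cases + controls, groups


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_expression_counts(config: SimulationConfig,
                               truth: SyntheticTruth) -> CountMatrix:
    """Negative-binomial gene counts; planted genes get case means scaled by
    ``2^lfc``; per-sample library factors applied; seed-deterministic."""
    rng = _rng(config, _STAGE_EXPRESSION)
    samples, groups = _sample_names_groups(config)
    gene_ids = _gene_ids(config)
    base = config.baseline_mean_expr * 2.0 ** rng.normal(0.0, 0.5, config.n_genes)
    lfc = np.array([truth.de_genes.get(g, 0.0) for g in gene_ids])
    factors = _library_factors(config, rng)
    is_case = np.array([groups[s] == "case" for s in samples])
    mean_matrix = base[:, None] * np.where(is_case[None, :], 2.0 ** lfc[:, None], 1.0)
    mean_matrix = mean_matrix * factors[None, :]
    counts = _nb_draw(rng, mean_matrix, config.nb_dispersion)
    return CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=samples), groups)


def simulate_methylation_counts(config: SimulationConfig, truth: SyntheticTruth,
                                annotation: list[GeneAnnotation]) -> CountMatrix:
    """Region-level methylation counts over ``gene|promoter``, ``gene|exon``
    and ``gene|body`` ids; planted promoters get case means scaled by
    ``2^lfc_dm``."""
    rng = _rng(config, _STAGE_METHYLATION)
    samples, groups = _sample_names_groups(config)
    regions = gene_region_set(annotation)
    region_ids = [r.region_id for r in regions]
    base = config.baseline_mean_meth * 2.0 ** rng.normal(0.0, 0.5, len(regions))
    lfc = np.array([
        truth.dm_promoters.get(r.gene_id, 0.0) if r.kind == "promoter" else 0.0
        for r in regions
    ])
    factors = _library_factors(config, rng)
    is_case = np.array([groups[s] == "case" for s in samples])
    mean_matrix = base[:, None] * np.where(is_case[None, :], 2.0 ** lfc[:, None], 1.0)
    mean_matrix = mean_matrix * factors[None, :]
    counts = _nb_draw(rng, mean_matrix, config.nb_dispersion)
    return CountMatrix(pd.DataFrame(counts, index=region_ids, columns=samples), groups)


def simulate_trn(config: SimulationConfig, truth: SyntheticTruth) -> RegulatoryNetwork:
    """Directed hub network: each TF points at its regulon members."""
    import networkx as nx

    graph = nx.DiGraph()
    for tf, regulon in truth.tf_regulons.items():
        for target in regulon:
            graph.add_edge(tf, target)
    return RegulatoryNetwork(graph=graph, self_loops=[])


def simulate_compound_signatures(config: SimulationConfig,
                                 truth: SyntheticTruth) -> CompoundSignatureSet:
    """Standard-normal score vectors per (compound, context, replicate);
    planted hit compounds shift their target TF's score by
    ``+-compound_effect_size`` in every replicate of the hit context."""
    rng = _rng(config, _STAGE_SIGNATURES)
    gene_ids = _gene_ids(config)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    compounds = [f"cpd{i:04d}" for i in range(config.n_compounds)]
    scores: dict[tuple[str, str], np.ndarray] = {}
    for compound in compounds:
        for context in config.cell_contexts:
            scores[(compound, context)] = rng.standard_normal(
                (config.n_genes, config.n_replicates_per_signature))
    for hit in truth.compound_hits:
        arr = scores[(hit["compound"], hit["context"])]
        shift = config.compound_effect_size if hit["direction"] == "up" \
            else -config.compound_effect_size
        arr[gene_pos[hit["tf"]], :] += shift
    return CompoundSignatureSet(gene_ids, scores)


def simulate_dataset(config: SimulationConfig) -> dict:
    """Run every generator stage and return the full in-memory dataset."""
    truth = plan_truth(config)
    annotation = simulate_annotation(config)
    return {
        "config": config,
        "truth": truth,
        "annotation": annotation,
        "expression": simulate_expression_counts(config, truth),
        "methylation": simulate_methylation_counts(config, truth, annotation),
        "network": simulate_trn(config, truth),
        "signatures": simulate_compound_signatures(config, truth),
    }


def simulate_mediation_chain(n_genes: int, n_case: int, n_control: int,
                             a: float, b: float, noise_sd: float,
                             seed: int) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, float]:
    """Gaussian mediation chain on the log scale for model calibration.

    methylation = a * group + noise; expression = b * methylation + noise.
    Returns (expr_log, meth_log, group_code, true_indirect = a * b).
    """
    rng = np.random.default_rng(seed)
    g = np.array([1] * n_case + [0] * n_control)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    meth = a * g[None, :] + rng.normal(0.0, noise_sd, (n_genes, g.size))
    expr = b * meth + rng.normal(0.0, noise_sd, (n_genes, g.size))
    cols = [f"s{j}" for j in range(g.size)]
    return (pd.DataFrame(expr, index=genes, columns=cols),
            pd.DataFrame(meth, index=genes, columns=cols),
            g, a * b)


def write_dataset(dataset: dict, outdir: str | Path) -> None:
    """Write the full synthetic bundle the way the CLI's simulate command does."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_gene_annotation_gtf(dataset["annotation"], outdir / "annotation.gtf")
    mio.write_count_matrix(dataset["expression"], outdir / "expr_counts.tsv")
    mio.write_count_matrix(dataset["methylation"], outdir / "meth_counts.tsv")
    mio.write_groups(dict(dataset["expression"].groups), outdir / "groups.tsv")
    mio.write_network(dataset["network"], outdir / "trn.tsv")
    mio.write_signature_dir(dataset["signatures"], outdir / "signatures")
    truth = dataset["truth"]
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(truth), fh, indent=2, sort_keys=True)
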