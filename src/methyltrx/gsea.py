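"""Preranked gene set enrichment with the weighted Kolmogorov-Smirnov statistic.

The coupling question — are genes with differentially methylated promoters,
exons or gene bodies collectively shifted in the expression ranking? — is
answered by building a signed ranking from the expression differential test
(score = sign(log2fc) * -log10 p), one gene set per region kind from the
methylation differential test, and a weighted-KS running sum whose extremum
is the enrichment score.  Significance comes from gene-tag permutation:
uniformly resampled sets of the same size, with the p-value computed among
same-sign null scores and BH adjustment across the sets evaluated together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ValidationError
from .diffstats import bh_fdr
from .regions import parse_region_id

logger = logging.getLogger(__name__)

_MIN_POSITIVE = np.nextafter(0.0, 1.0)


@dataclass
class RankedList:
    """Genes ordered best-upregulated first with their signed scores."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValidationError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in ranked list")
        if np.any(np.diff(self.scores) > 0):
            raise ValidationError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.genes, name="score")


@dataclass
class EnrichmentResult:
    set_name: str
    size: int
    es: float
    nes: float
    pvalue: float
    qvalue: float
    leading_edge: list[str] = field(default_factory=list)


def build_ranked_list(diff: pd.DataFrame, integer_ranks: bool = False) -> RankedList:
    """Signed ranking from a differential-expression result.

    Default metric: ``sign(log2fc) * -log10(pvalue)`` (p = 0 clamped to the
    smallest positive float; log2fc = 0 gives score 0).  With
    ``integer_ranks=True`` the scores are replaced by signed integer ranks
    preserving the same order, the literal reading of ranking genes by
    p-value with positive numbers for upregulated genes.  Features with
    missing p are skipped with a warning.  Ties break lexicographically by
    gene id.
    """
    usable = diff.dropna(subset=["pvalue"])
    n_skipped = len(diff) - len(usable)
    if n_skipped:
        logger.warning("build_ranked_list: skipped %d features with missing p", n_skipped)
    p = np.clip(usable["pvalue"].to_numpy(float), _MIN_POSITIVE, 1.0)
    sign = np.sign(usable["log2fc"].to_numpy(float))
    scores = sign * (-np.log10(p))
    scores[scores == 0.0] = 0.0  # normalize -0.0
    frame = pd.DataFrame({"gene": usable["feature_id"].to_numpy(), "score": scores})
    frame = frame.sort_values(["score", "gene"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    if integer_ranks:
        n = len(frame)
        frame["score"] = np.arange(n, 0, -1, dtype=float) - (n + 1) / 2.0
    return RankedList(list(frame["gene"]), frame["score"].to_numpy())


def build_methylation_gene_sets(meth_diff: pd.DataFrame,
                                q_threshold: float = 0.05) -> dict[str, set[str]]:
    """One gene set per region kind from region-level methylation calls.

    A gene enters set ``kind`` when its region ``gene|kind`` has
    ``qvalue < q_threshold``.  Empty sets are permitted but logged.
    """
    sets: dict[str, set[str]] = {"promoter": set(), "exon": set(), "body": set()}
    for _, row in meth_diff.iterrows():
        gene_id, kind = parse_region_id(str(row["feature_id"]))
        q = row["qvalue"]
        if pd.notna(q) and q < q_threshold:
            sets[kind].add(gene_id)
    for kind, members in sets.items():
        if not members:
            logger.warning("methylation gene set %r is empty at q < %g", kind, q_threshold)
    return sets


def _hit_mask(ranked: RankedList, gene_set: set[str]) -> np.ndarray:
    genes = np.asarray(ranked.genes)
    mask = np.isin(genes, sorted(gene_set))
    n_hits = int(mask.sum())
    if n_hits == 0:
        raise ValidationError("gene set does not intersect the ranked list")
    if n_hits == len(ranked):
        raise ValidationError("gene set equals the ranked universe; misses undefined")
    return mask


def _es_from_mask(scores: np.ndarray, mask: np.ndarray, weight: float
                  ) -> tuple[float, np.ndarray, int]:
    """Running sum, extremum and extremum index for one hit mask (O(N))."""
    n = scores.size
    n_hits = int(mask.sum())
    weights = np.abs(scores[mask]) ** weight
    total = weights.sum()
    steps = np.full(n, -1.0 / (n - n_hits))
    if total > 0:
        steps[mask] = weights / total
    else:  # all hit scores zero: equal hit increments
        steps[mask] = 1.0 / n_hits
    running = np.cumsum(steps)
    idx_max = int(np.argmax(running))
    idx_min = int(np.argmin(running))
    peak, trough = running[idx_max], running[idx_min]
    # Sign ties (|peak| == |trough|) resolve toward the positive deviation.
    if peak >= -trough:
        return float(peak), running, idx_max
    return float(trough), running, idx_min


def gsea_enrichment_score(ranked: RankedList, gene_set: set[str],
                          weight: float = 1.0
                          ) -> tuple[float, np.ndarray, list[str]]:
    """Weighted-KS enrichment score, running sum and leading edge.

    Walking the ranking, each hit adds ``|score|^weight / sum_hits
    |score|^weight`` and each miss subtracts ``1 / (N - N_hits)``; the ES is
    the running-sum value of maximal absolute deviation.  The leading edge
    contains the hits at or before the extremum (at or after it, for a
    negative ES).
    """
    mask = _hit_mask(ranked, gene_set)
    es, running, idx = _es_from_mask(ranked.scores, mask, weight)
    genes = np.asarray(ranked.genes)
    if es >= 0:
        leading = genes[: idx + 1][mask[: idx + 1]]
    else:
        leading = genes[idx + 1:][mask[idx + 1:]]
    return es, running, list(leading)


def _null_es(scores: np.ndarray, set_size: int, n_perm: int,
             rng: np.random.Generator, weight: float) -> np.ndarray:
    """ES of uniformly resampled gene sets of the given size (gene-tag
    permutation)."""
    n = scores.size
    out = np.empty(n_perm)
    mask = np.zeros(n, dtype=bool)
    for b in range(n_perm):
        idx = rng.choice(n, size=set_size, replace=False)
        mask[:] = False
        mask[idx] = True
        out[b], _, _ = _es_from_mask(scores, mask, weight)
    return out


def gsea_significance(ranked: RankedList, gene_sets: dict[str, set[str]],
                      n_perm: int = 1000, seed: int | None = None,
                      weight: float = 1.0) -> list[EnrichmentResult]:
    """Permutation significance for each gene set, BH-adjusted across the call.

    For each set the null is the ES distribution of ``n_perm`` uniformly
    resampled same-size sets; ``p = (1 + #{|null same-sign| >= |es|}) /
    (1 + #same-sign nulls)`` and ``nes = es / mean(|same-sign nulls|)``.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    results: list[EnrichmentResult] = []
    for name in sorted(gene_sets):
        gene_set = gene_sets[name]
        mask = _hit_mask(ranked, gene_set)
        size = int(mask.sum())
        es, _, leading = gsea_enrichment_score(ranked, gene_set, weight)
        null = _null_es(ranked.scores, size, n_perm, rng, weight)
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        n_same = same_sign.size
        p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + n_same)
        mean_null = np.mean(np.abs(same_sign)) if n_same else np.nan
        nes = es / mean_null if n_same and mean_null > 0 else np.nan
        results.append(EnrichmentResult(name, size, es, nes, float(p), np.nan, leading))
    qvalues = bh_fdr([r.pvalue for r in results])
    for r, q in zip(results, qvalues):
        r.qvalue = float(q)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "set_name": [r.set_name for r in results],
        "size": [r.size for r in results],
        "ES": [r.es for r in results],
        "NES": [r.nes for r in results],
        "pval": [r.pvalue for r in results],
        "FDR_q": [r.qvalue for r in results],
        "leading_edge": [",".join(r.leading_edge) for r in results],
    })
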