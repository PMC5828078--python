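"""Connectivity-map-style compound query over file-based signature matrices.

For each (compound, cell context) the replicate score vectors are z-scored
per replicate and collapsed to a per-gene median consensus; a compound is a
hit for a transcription factor when the TF sits among the k most up- or
k most down-regulated genes of that consensus (k = 100 by default, ties at
the boundary broken lexicographically by gene id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CompoundSignatureSet, ValidationError


@dataclass(frozen=True)
class CompoundHit:
    compound_id: str
    context: str
    direction: str  # "up" or "down"
    tf_rank: int    # 1-based rank from the relevant extreme
    n_genes: int


def consensus_signature(replicates: np.ndarray) -> np.ndarray:
    """Median across replicates of per-replicate z-scored score vectors.

    ``replicates`` is genes x replicates; a single replicate returns its own
    z-scored vector.  Z-scoring uses the population standard deviation over
    genes; a constant replicate is rejected.
    """
    arr = np.asarray(replicates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    sd = arr.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValidationError("constant replicate signature cannot be z-scored")
    z = (arr - arr.mean(axis=0)) / sd
    return np.median(z, axis=1)


def top_k_membership(signature: np.ndarray, genes: pd.Index, gene: str,
                     k: int = 100) -> tuple[str, int]:
    """Is ``gene`` among the k most up- or down-regulated entries?

    Returns ``(direction, rank)`` where direction is "up", "down" or "none"
    and rank is 1-based from the top for "up"/"none" and from the bottom for
    "down".  Ranking is by descending score with lexicographic gene-id
    tie-breaking; ``k`` must satisfy ``k < n_genes / 2`` so the two
    directions cannot overlap.
    """
    n = len(genes)
    if k >= n / 2:
        raise ValidationError(f"k={k} must be < n_genes/2 = {n / 2:g}")
    if gene not in genes:
        raise ValidationError(f"{gene!r} not in the signature gene universe")
    order = np.lexsort((np.asarray(genes), -np.asarray(signature, dtype=float)))
    pos = int(np.flatnonzero(np.asarray(genes)[order] == gene)[0])
    rank_from_top = pos + 1
    rank_from_bottom = n - pos
    if rank_from_top <= k:
        return "up", rank_from_top
    if rank_from_bottom <= k:
        return "down", rank_from_bottom
    return "none", rank_from_top


def query_compounds(signatures: CompoundSignatureSet, tf: str,
                    k: int = 100) -> list[CompoundHit]:
    """All (compound, context) pairs whose consensus places ``tf`` in the
    top-k up or down tail, sorted by (compound, context)."""
    if tf not in signatures.genes:
        raise ValidationError(f"{tf!r} not in the signature gene universe")
    hits: list[CompoundHit] = []
    n = signatures.n_genes()
    for (compound, context) in sorted(signatures.scores):
        consensus = consensus_signature(signatures.scores[(compound, context)])
        direction, rank = top_k_membership(consensus, signatures.genes, tf, k)
        if direction != "none":
            hits.append(CompoundHit(compound, context, direction, rank, n))
    return hits


def hits_table(hits: list[CompoundHit], tf: str | None = None) -> pd.DataFrame:
    """Flat hit list; a lossless reshaping of the per-context memberships."""
    df = pd.DataFrame({
        "compound": [h.compound_id for h in hits],
        "context": [h.context for h in hits],
        "direction": [h.direction for h in hits],
        "tf_rank": [h.tf_rank for h in hits],
        "n_genes": [h.n_genes for h in hits],
    })
    if tf is not None:
        df.insert(0, "tf", tf)
    return df
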