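"""Overlay differential expression on a transcription regulatory network.

Dysregulated transcription factors (FDR < 0.05 and |log2FC| > 1, strict)
are selected among network nodes with outgoing edges; each TF's direct
out-neighbors form its regulon, and targets with FDR < 0.05 are tabulated
as up- or down-regulated by the sign of their fold-change.  TFs are ranked
by the number of altered targets, and the same-direction targets shared
between two brain regions can be intersected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import RegulatoryNetwork, ValidationError


@dataclass
class TfTargetSummary:
    tf_id: str
    tf_log2fc: float
    tf_q: float
    n_targets_total: int
    up_targets: list[str] = field(default_factory=list)
    down_targets: list[str] = field(default_factory=list)

    @property
    def n_altered(self) -> int:
        return len(self.up_targets) + len(self.down_targets)


def _de_lookup(de: pd.DataFrame) -> pd.DataFrame:
    return de.set_index("feature_id")


def select_dysregulated_tfs(de: pd.DataFrame, network: RegulatoryNetwork,
                            q_max: float = 0.05, lfc_min: float = 1.0
                            ) -> list[str]:
    """TFs (out-degree >= 1) with q < q_max and |log2fc| > lfc_min, both strict."""
    table = _de_lookup(de)
    selected = []
    for tf in network.tfs():
        if tf not in table.index:
            continue
        row = table.loc[tf]
        if pd.notna(row["qvalue"]) and row["qvalue"] < q_max \
                and abs(row["log2fc"]) > lfc_min:
            selected.append(tf)
    return selected


def tf_target_summary(tf: str, network: RegulatoryNetwork, de: pd.DataFrame,
                      target_q_max: float = 0.05) -> TfTargetSummary:
    """Classify a TF's direct out-neighbors as up/down-regulated targets.

    A target is altered when its q < target_q_max (no fold-change threshold
    on targets); direction follows the sign of its log2fc.  Targets missing
    from the differential table count in the total but are never altered.
    """
    targets = network.targets_of(tf)
    if not targets:
        raise ValidationError(f"{tf!r} has no outgoing edges; not a TF here")
    table = _de_lookup(de)
    up, down = [], []
    for target in targets:
        if target not in table.index:
            continue
        row = table.loc[target]
        if pd.isna(row["qvalue"]) or row["qvalue"] >= target_q_max:
            continue
        if row["log2fc"] > 0:
            up.append(target)
        elif row["log2fc"] < 0:
            down.append(target)
    tf_lfc, tf_q = float("nan"), float("nan")
    if tf in table.index:
        tf_lfc = float(table.loc[tf, "log2fc"])
        tf_q = float(table.loc[tf, "qvalue"])
    return TfTargetSummary(tf, tf_lfc, tf_q, len(targets), up, down)


def rank_tfs_by_altered_targets(summaries: list[TfTargetSummary],
                                top_n: int = 4) -> list[str]:
    """Descending by altered-target count; ties by altered fraction then id."""
    def key(s: TfTargetSummary):
        frac = s.n_altered / s.n_targets_total if s.n_targets_total else 0.0
        return (-s.n_altered, -frac, s.tf_id)
    ordered = sorted(summaries, key=key)
    return [s.tf_id for s in ordered[:top_n]]


def cross_region_shared_targets(summaries_region1: list[TfTargetSummary],
                                summaries_region2: list[TfTargetSummary]
                                ) -> dict[str, dict[str, list[str]]]:
    """Per TF, targets altered in the same direction in both regions."""
    by_tf2 = {s.tf_id: s for s in summaries_region2}
    shared: dict[str, dict[str, list[str]]] = {}
    for s1 in summaries_region1:
        s2 = by_tf2.get(s1.tf_id)
        if s2 is None:
            continue
        shared[s1.tf_id] = {
            "up": sorted(set(s1.up_targets) & set(s2.up_targets)),
            "down": sorted(set(s1.down_targets) & set(s2.down_targets)),
        }
    return shared


def summaries_table(summaries: list[TfTargetSummary]) -> pd.DataFrame:
    """Tabular view mirroring a per-TF altered-targets report."""
    return pd.DataFrame({
        "TF": [s.tf_id for s in summaries],
        "log2FC": [s.tf_log2fc for s in summaries],
        "FDR": [s.tf_q for s in summaries],
        "altered_targets": [s.n_altered for s in summaries],
        "all_targets": [s.n_targets_total for s in summaries],
        "up_targets": [",".join(s.up_targets) for s in summaries],
        "down_targets": [",".join(s.down_targets) for s in summaries],
    })
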