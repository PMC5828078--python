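"""Small statistics used for wet-lab validation of sequencing calls.

Mann-Whitney U (exact for small tie-free samples), ddPCR reference-gene
normalization with a fold-change of group means, pyrosequencing percent
methylation, and the Spearman marker-correlation check used to relate TF
expression to cell-type marker genes.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core import ValidationError

EXACT_MAX_TOTAL_N = 12


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U statistic and p-value.

    ``U = #{(i, j): x_i > y_j} + 0.5 * #ties``.  The p-value is exact (full
    enumeration) when ``n_x + n_y <= 12`` and there are no ties between or
    within samples; otherwise the normal approximation with tie correction
    and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("measurements must be finite")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= EXACT_MAX_TOTAL_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def ddpcr_log2fc(target_conc, ref_conc, groups) -> tuple[float, float]:
    """ddPCR fold-change after reference-gene normalization.

    Each sample's target concentration (copies/ul) is divided by its
    reference-gene concentration; the log2 fold-change is taken between the
    case and control means of the normalized values, and the p-value is a
    Mann-Whitney U test on them.
    """
    target = np.asarray(target_conc, dtype=float)
    ref = np.asarray(ref_conc, dtype=float)
    groups = np.asarray(groups)
    if target.shape != ref.shape or target.shape != groups.shape:
        raise ValidationError("target, reference and groups must align per sample")
    if np.any(ref <= 0):
        raise ValidationError("reference concentrations must be positive")
    normalized = target / ref
    case = normalized[groups == "case"]
    control = normalized[groups == "control"]
    if case.size == 0 or control.size == 0:
        raise ValidationError("both groups must be represented")
    log2fc = float(np.log2(case.mean() / control.mean()))
    _, p = mann_whitney_u(case, control)
    return log2fc, p


def percent_methylation(meth_signal: float, unmeth_signal: float,
                        literal_ratio: bool = False) -> float:
    """Percent methylation at a CpG site.

    Default: ``100 * meth / (meth + unmeth)``, the conventional bounded
    percentage.  ``literal_ratio=True`` instead returns
    ``100 * meth / unmeth`` (unbounded; requires unmeth > 0).
    """
    if meth_signal < 0 or unmeth_signal < 0:
        raise ValidationError("signals must be non-negative")
    if meth_signal == 0 and unmeth_signal == 0:
        raise ValidationError("both signals zero; percentage undefined")
    if literal_ratio:
        if unmeth_signal == 0:
            raise ValidationError("literal ratio undefined for zero unmethylated signal")
        return 100.0 * meth_signal / unmeth_signal
    return 100.0 * meth_signal / (meth_signal + unmeth_signal)


def marker_correlation(tf_counts, marker_counts) -> tuple[float, float]:
    """Spearman rank correlation between TF and marker normalized counts.

    Returns (rho, two-sided p); requires n >= 4; a constant vector yields
    missing rho (NaN, NaN).
    """
    x = np.asarray(tf_counts, dtype=float)
    y = np.asarray(marker_counts, dtype=float)
    if x.size != y.size:
        raise ValidationError("vectors must have equal length")
    if x.size < 4:
        raise ValidationError("at least 4 paired samples required")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
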