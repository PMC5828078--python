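"""Count normalization and per-feature differential testing.

One engine serves both the expression (gene x sample) and the methylation
(region x sample) arms: median-of-ratios size factors, a negative-binomial
Wald test with method-of-moments dispersion, Benjamini-Hochberg FDR, and
the low-count filter applied before the regression stage.

The Wald test here is deliberately simple and fully specified: normalized
group means, a dispersion pooled within groups, a pseudo-count of 0.5 in
the fold-change, and a t reference with ``n1 + n2 - 2`` degrees of freedom
to account for the dispersion being estimated from few samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DIFF_COLUMNS,
    GROUP_CASE,
    GROUP_CONTROL,
    CountMatrix,
    ValidationError,
)

DISPERSION_FLOOR = 1e-8
PSEUDO_COUNT = 0.5


def size_factors_median_of_ratios(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors, rescaled to geometric mean 1.

    The reference for sample ``j`` is the per-feature geometric mean over
    samples; only features positive in every sample enter the median.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    mat = df.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValidationError(
            "no feature has positive counts in every sample; "
            "median-of-ratios undefined (consider a total-count fallback)"
        )
    ref = np.exp(np.mean(np.log(mat[all_positive]), axis=1))
    factors = np.median(mat[all_positive] / ref[:, None], axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="size_factor")


def normalize_counts(counts: CountMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Counts divided by size factors; returns (normalized frame, factors)."""
    factors = size_factors_median_of_ratios(counts)
    return counts.counts / factors, factors


def bh_fdr(pvalues: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing values (NaN) pass through unchanged and do not count toward the
    number of tests.  Output preserves input order.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    out[mask] = q
    return out


def _group_arrays(counts: CountMatrix, normalized: pd.DataFrame
                  ) -> tuple[np.ndarray, np.ndarray]:
    case = normalized[counts.samples_in_group(GROUP_CASE)].to_numpy(float)
    control = normalized[counts.samples_in_group(GROUP_CONTROL)].to_numpy(float)
    return case, control


def nb_wald_test(counts: CountMatrix, min_mean: float = 0.0) -> pd.DataFrame:
    """Per-feature two-group Wald test under a negative-binomial noise model.

    For each feature the counts are normalized by median-of-ratios size
    factors; a common dispersion ``alpha`` is estimated by method of moments
    from the within-group variances, floored at ``1e-8`` (Poisson limit);
    the effect is ``log2fc = log2((mean_case + 0.5) / (mean_control + 0.5))``
    on the normalized scale; its standard error comes from the NB variance
    function ``mu + alpha * mu^2`` via the delta method; two-sided p-values
    use a t reference with ``n1 + n2 - 2`` degrees of freedom.  BH q-values
    are appended over all tested features.  Features whose normalized mean
    falls below ``min_mean``, and all-zero features, are reported with
    missing p and q.
    """
    counts.require_min_group_size(2)
    normalized, _ = normalize_counts(counts)
    case, control = _group_arrays(counts, normalized)
    n1, n2 = case.shape[1], control.shape[1]

    mu1 = case.mean(axis=1)
    mu2 = control.mean(axis=1)
    base_mean = normalized.mean(axis=1).to_numpy()
    log2fc = np.log2((mu1 + PSEUDO_COUNT) / (mu2 + PSEUDO_COUNT))

    # Method-of-moments dispersion pooled within groups:
    # Var = mu + alpha mu^2  =>  alpha = (s^2 - mu) / mu^2, averaged with
    # within-group degrees of freedom as weights.
    s2_1 = case.var(axis=1, ddof=1)
    s2_2 = control.var(axis=1, ddof=1)
    num = (n1 - 1) * (s2_1 - mu1) + (n2 - 1) * (s2_2 - mu2)
    den = (n1 - 1) * mu1**2 + (n2 - 1) * mu2**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    var_mean1 = (mu1 + alpha * mu1**2) / n1
    var_mean2 = (mu2 + alpha * mu2**2) / n2
    ln2 = np.log(2.0)
    se = np.sqrt(var_mean1 / (mu1 + PSEUDO_COUNT) ** 2
                 + var_mean2 / (mu2 + PSEUDO_COUNT) ** 2) / ln2

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    df = n1 + n2 - 2
    pvalues = 2.0 * stats.t.sf(np.abs(wald), df)
    pvalues = np.minimum(pvalues, 1.0)

    testable = (base_mean >= min_mean) & ((mu1 > 0) | (mu2 > 0))
    pvalues = np.where(testable, pvalues, np.nan)
    qvalues = bh_fdr(pvalues)

    return pd.DataFrame({
        "feature_id": counts.feature_ids,
        "mean_count": base_mean,
        "log2fc": log2fc,
        "pvalue": pvalues,
        "qvalue": qvalues,
    }, columns=DIFF_COLUMNS)


def filter_low_expression(obj: CountMatrix | pd.DataFrame,
                          min_mean: float = 50.0):
    """Drop features whose average raw count across all samples is below
    ``min_mean`` (strict ``<``; a mean of exactly ``min_mean`` is kept).

    Accepts a :class:`CountMatrix` (mean over raw counts) or a diff-result
    frame (mean over its ``mean_count`` column); returns the same type.
    """
    if isinstance(obj, CountMatrix):
        means = obj.counts.mean(axis=1)
        keep = means >= min_mean
        return CountMatrix(obj.counts.loc[keep], dict(obj.groups))
    means = obj["mean_count"]
    return obj.loc[means >= min_mean].reset_index(drop=True)
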