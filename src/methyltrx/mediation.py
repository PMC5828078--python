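"""Per-gene linear models linking injury status, promoter methylation and
expression.

Two models are fitted per gene on ``log2(normalized count + 1)`` values:

(a) expression ~ methylation — an ordinary least-squares slope with a
    two-sided t-test, asking whether methylation level tracks expression;
(b) injury -> expression via methylation — product-of-coefficients
    mediation: stage 1 regresses methylation on group (coefficient ``a``),
    stage 2 regresses expression on methylation and group (coefficients
    ``b`` and the direct effect); the indirect effect is ``a * b`` with a
    percentile bootstrap (samples resampled within groups) supplying the
    95% CI and a two-sided p-value.

Genes whose average raw expression count is below 50 are filtered out
before testing, and BH q-values are computed over the tested genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GROUP_CASE, CountMatrix, ValidationError
from .diffstats import bh_fdr, normalize_counts
from .regions import parse_region_id


@dataclass
class MediationResult:
    gene_id: str
    a: float            # group -> methylation
    b: float            # methylation -> expression, group-adjusted
    direct: float       # group -> expression, methylation-adjusted
    indirect: float     # a * b
    ci_low: float
    ci_high: float
    pvalue: float
    qvalue: float = np.nan


def log2_normalized(counts: CountMatrix) -> pd.DataFrame:
    """``log2(count / size_factor + 1)`` — the working scale of both models."""
    normalized, _ = normalize_counts(counts)
    return np.log2(normalized + 1.0)


def promoter_pairing(meth_features: list[str], kind: str = "promoter"
                     ) -> dict[str, str]:
    """Map gene id -> region id for one region kind from ``gene|kind`` ids."""
    pairing: dict[str, str] = {}
    for region_id in meth_features:
        gene_id, region_kind = parse_region_id(region_id)
        if region_kind == kind:
            pairing[gene_id] = region_id
    return pairing


def _aligned_log_matrices(expr: CountMatrix, meth: CountMatrix,
                          pairing: dict[str, str], min_mean: float
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    if list(expr.sample_ids) != list(meth.sample_ids):
        if set(expr.sample_ids) != set(meth.sample_ids):
            raise ValidationError("expression and methylation matrices must share samples")
        meth = CountMatrix(meth.counts[expr.sample_ids], dict(meth.groups))
    raw_means = expr.counts.mean(axis=1)
    genes = [g for g in expr.feature_ids
             if g in pairing and pairing[g] in meth.counts.index
             and raw_means[g] >= min_mean]
    expr_log = log2_normalized(expr).loc[genes]
    meth_log = log2_normalized(meth).loc[[pairing[g] for g in genes]]
    meth_log.index = genes
    return expr_log, meth_log, expr.groups


def regress_methylation_on_expression(expr: CountMatrix, meth: CountMatrix,
                                      pairing: dict[str, str],
                                      min_mean: float = 50.0) -> pd.DataFrame:
    """Model (a): per-gene OLS of expression on paired methylation.

    Returns a frame with slope estimate, 95% CI, t-test p and BH q.  Genes
    with zero-variance methylation are reported with missing statistics.
    """
    expr_log, meth_log, _ = _aligned_log_matrices(expr, meth, pairing, min_mean)
    n = expr_log.shape[1]
    if n < 3:
        raise ValidationError("at least 3 samples required for regression")
    x = meth_log.to_numpy()
    y = expr_log.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = (xc**2).sum(axis=1)
    # relative tolerance: rounding residue from the log transform is not variance
    degenerate = sxx <= 1e-18 * np.maximum(1.0, (x**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(degenerate, np.nan, (xc * yc).sum(axis=1) / sxx)
        resid = yc - np.where(np.isnan(slope), 0.0, slope)[:, None] * xc
        sigma2 = (resid**2).sum(axis=1) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
    tstat = slope / se
    pvalues = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    tcrit = stats.t.ppf(0.975, n - 2)
    return pd.DataFrame({
        "gene_id": expr_log.index,
        "slope": slope,
        "ci_low": slope - tcrit * se,
        "ci_high": slope + tcrit * se,
        "pvalue": pvalues,
        "qvalue": bh_fdr(pvalues),
    }).reset_index(drop=True)


def _mediation_coefs(y: np.ndarray, x: np.ndarray, g: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form per-gene coefficients for both mediation stages.

    ``y``/``x`` are genes x samples log matrices, ``g`` the 0/1 group code.
    Stage 2 uses Frisch-Waugh: residualize x and y on group, then
    ``b = cov(x_r, y_r) / var(x_r)``; the direct effect follows from the
    group-mean decomposition ``total = direct + a * b``.
    """
    n1 = g.sum()
    n0 = g.size - n1
    mean1 = lambda m: m[:, g == 1].mean(axis=1)
    mean0 = lambda m: m[:, g == 0].mean(axis=1)
    a = mean1(x) - mean0(x)
    total = mean1(y) - mean0(y)
    group_means_x = np.where(g == 1, mean1(x)[:, None], mean0(x)[:, None])
    group_means_y = np.where(g == 1, mean1(y)[:, None], mean0(y)[:, None])
    xr = x - group_means_x
    yr = y - group_means_y
    sxx = (xr**2).sum(axis=1)
    degenerate = sxx <= 1e-18 * np.maximum(1.0, (x**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(degenerate, np.nan, (xr * yr).sum(axis=1) / sxx)
    direct = total - a * b
    return a, b, direct


def mediation_tbi_via_methylation(expr: CountMatrix, meth: CountMatrix,
                                  pairing: dict[str, str],
                                  min_mean: float = 50.0,
                                  n_boot: int = 2000,
                                  seed: int | None = None) -> pd.DataFrame:
    """Model (b): indirect effect of injury on expression through methylation.

    Percentile bootstrap: samples are resampled with replacement within each
    group (the same resample applied to every gene), both stages refitted,
    and the 2.5/97.5 percentiles of the ``a*b`` replicates give the CI; the
    two-sided p is twice the smaller tail proportion of replicates on either
    side of zero (with +1 smoothing), so it is seed-deterministic.
    """
    expr_log, meth_log, groups = _aligned_log_matrices(expr, meth, pairing, min_mean)
    g = (groups == GROUP_CASE).to_numpy().astype(int)
    if (g == 1).sum() < 3 or (g == 0).sum() < 3:
        raise ValidationError("each group needs at least 3 samples for mediation")
    return mediation_from_log_matrices(expr_log, meth_log, g, n_boot=n_boot, seed=seed)


def mediation_from_log_matrices(expr_log: pd.DataFrame, meth_log: pd.DataFrame,
                                group_code: np.ndarray, n_boot: int = 2000,
                                seed: int | None = None) -> pd.DataFrame:
    """Mediation on already log-transformed, sample-aligned matrices.

    ``group_code`` is 0/1 per sample (1 = case).  Exposed separately so the
    models can be exercised on directly simulated Gaussian chains as well as
    on count data.
    """
    if not expr_log.index.equals(meth_log.index):
        raise ValidationError("expression and methylation rows must pair one-to-one")
    y = expr_log.to_numpy(float)
    x = meth_log.to_numpy(float)
    g = np.asarray(group_code, dtype=int)
    a, b, direct = _mediation_coefs(y, x, g)
    indirect = a * b

    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(g == 1)
    idx0 = np.flatnonzero(g == 0)
    boot = np.empty((n_boot, y.shape[0]))
    for r in range(n_boot):
        take = np.concatenate([rng.choice(idx1, size=idx1.size, replace=True),
                               rng.choice(idx0, size=idx0.size, replace=True)])
        ab, bb, _ = _mediation_coefs(y[:, take], x[:, take], g[take])
        boot[r] = ab * bb
    valid = ~np.isnan(boot)
    any_valid = valid.any(axis=0)
    ci_low = np.full(boot.shape[1], np.nan)
    ci_high = np.full(boot.shape[1], np.nan)
    with np.errstate(invalid="ignore"):
        if any_valid.any():
            ci_low[any_valid] = np.nanpercentile(boot[:, any_valid], 2.5, axis=0)
            ci_high[any_valid] = np.nanpercentile(boot[:, any_valid], 97.5, axis=0)
        n_valid = valid.sum(axis=0)
        n_le = (boot <= 0).sum(axis=0, where=valid)
        n_ge = (boot >= 0).sum(axis=0, where=valid)
    pvalues = np.minimum(1.0, 2.0 * np.minimum(
        (n_le + 1) / (n_valid + 1), (n_ge + 1) / (n_valid + 1)))
    pvalues = np.where(np.isnan(indirect), np.nan, pvalues)
    out = pd.DataFrame({
        "gene_id": expr_log.index,
        "a": a,
        "b": b,
        "direct": direct,
        "indirect": indirect,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "pvalue": pvalues,
        "qvalue": bh_fdr(pvalues),
    }).reset_index(drop=True)
    return out
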