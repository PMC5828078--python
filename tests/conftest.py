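"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from methyltrx.core import CountMatrix


@pytest.fixture
def toy_counts() -> CountMatrix:
    """4 features x 4 samples with obvious group structure."""
    df = pd.DataFrame(
        {
            "c1": [10, 100, 0, 50],
            "c2": [12, 110, 0, 55],
            "k1": [11, 10, 0, 50],
            "k2": [9, 12, 0, 52],
        },
        index=["flat", "up", "zero", "same"],
    )
    groups = {"c1": "case", "c2": "case", "k1": "control", "k2": "control"}
    return CountMatrix(df, groups)


def nb_count_matrix(seed: int, n_features: int = 500, n_per_group: int = 5,
                    mean: float = 200.0, dispersion: float = 0.1,
                    de_lfc: dict[int, float] | None = None) -> CountMatrix:
    """Minimal NB two-group sampler used as test scaffolding (independent of
    the package's own simulator)."""
    rng = np.random.default_rng(seed)
    mu = mean * 2.0 ** rng.normal(0.0, 0.5, n_features)
    mu_case = mu.copy()
    for i, lfc in (de_lfc or {}).items():
        mu_case[i] *= 2.0 ** lfc
    r = 1.0 / dispersion
    case = rng.negative_binomial(r, r / (r + mu_case[:, None]), (n_features, n_per_group))
    ctrl = rng.negative_binomial(r, r / (r + mu[:, None]), (n_features, n_per_group))
    samples = [f"c{j}" for j in range(n_per_group)] + [f"k{j}" for j in range(n_per_group)]
    df = pd.DataFrame(np.hstack([case, ctrl]),
                      index=[f"f{i:04d}" for i in range(n_features)], columns=samples)
    groups = {s: ("case" if s.startswith("c") else "control") for s in samples}
    return CountMatrix(df, groups)


def brute_force_es(ordered_genes: list[str], scores: np.ndarray,
                   gene_set: set[str], weight: float = 1.0) -> float:
    """Literal weighted-KS walk, written independently of the implementation:
    iterate the ranking, push hits up by normalized |score|^weight, misses
    down by 1/(N - N_hits), return the extremum (ties toward positive)."""
    hits = [g in gene_set for g in ordered_genes]
    n, n_h = len(ordered_genes), sum(hits)
    denom_hit = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    best_pos, best_neg, running = 0.0, 0.0, 0.0
    for s, h in zip(scores, hits):
        if h:
            running += (abs(s) ** weight / denom_hit) if denom_hit > 0 else 1.0 / n_h
        else:
            running -= 1.0 / (n - n_h)
        best_pos = max(best_pos, running)
        best_neg = min(best_neg, running)
    return best_pos if best_pos >= -best_neg else best_neg


def mwu_exact_two_sided(x: list[float], y: list[float]) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of group
    assignments (no ties assumed)."""
    pooled = list(x) + list(y)
    n_x = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    n_total, count_extreme = 0, 0
    u_null = []
    for combo in itertools.combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u_null.append(sum(1 for xi in xs for yj in ys if xi > yj))
        n_total += 1
    mean_u = n_x * (len(pooled) - n_x) / 2.0
    count_extreme = sum(1 for u in u_null if abs(u - mean_u) >= abs(u_obs - mean_u))
    return count_extreme / n_total
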