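"""Rank-based and permutation inference for per-embryo summaries.

Two tools: the Wilcoxon–Mann–Whitney rank-sum test (exact by full
enumeration of rank assignments, with midranks for ties, when the pooled
sample is small; a tie- and continuity-corrected normal approximation
otherwise), and an embryo-clustered permutation test on per-embryo
summaries — the embryo is the exchangeable unit, so group labels are
permuted across embryos, never across cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import norm, rankdata


@dataclass
class RankSumResult:
    """Wilcoxon–Mann–Whitney test outcome."""
    u_statistic: float            # U of the first sample
    p_two_sided: float
    method: str                   # "exact" | "normal_approx"
    n1: int
    n2: int
    tie_corrected: bool


@dataclass
class PermTestResult:
    """Embryo-clustered permutation test outcome."""
    observed: float               # difference of group means
    p: float
    n_permutations: int
    seed: int
    n1: int
    n2: int


def _u_statistic(ranks: np.ndarray, n1: int) -> float:
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def rank_sum_test(x, y, exact_limit: int = 16) -> RankSumResult:
    """Two-sided Wilcoxon–Mann–Whitney test of samples *x* vs *y*.

    Exact p-values enumerate all C(n1+n2, n1) assignments of the pooled
    midranks when n1+n2 <= ``exact_limit``; the two-sided p doubles the
    smaller tail (capped at 1). Larger samples use the normal
    approximation with tie correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank-sum test needs non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)              # midranks for ties
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    u_obs = _u_statistic(ranks, n1)
    n = n1 + n2

    if n <= exact_limit:
        idx = np.fromiter(
            (i for c in combinations(range(n), n1) for i in c), int,
            count=comb(n, n1) * n1).reshape(-1, n1)
        u_all = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        total = len(u_all)
        eps = 1e-9
        p_low = np.sum(u_all <= u_obs + eps) / total
        p_high = np.sum(u_all >= u_obs - eps) / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return RankSumResult(u_obs, float(p), "exact", n1, n2, has_ties)

    mu = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return RankSumResult(u_obs, 1.0, "normal_approx", n1, n2, has_ties)
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(max(z, 0.0)))
    return RankSumResult(u_obs, float(p), "normal_approx", n1, n2, has_ties)


def cluster_permutation_test(values, groups, n_perm: int = 10000,
                             seed: int = 0) -> PermTestResult:
    """Permutation test of a group difference in per-embryo summaries.

    *values* are one summary per embryo; *groups* the two group labels.
    The statistic is the difference of group means; the p-value is
    ``(1 + #{|permuted| >= |observed|}) / (n_perm + 1)`` under random
    relabelling of embryos, so it is valid and never zero.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    m1 = groups == labels[0]
    n1, n2 = int(m1.sum()), int((~m1).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 embryos")
    obs = values[m1].mean() - values[~m1].mean()

    rng = np.random.default_rng((seed, 53))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(values))
        pm = np.zeros(len(values), bool)
        pm[perm[:n1]] = True
        stat = values[pm].mean() - values[~pm].mean()
        if abs(stat) >= abs(obs) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermTestResult(observed=float(obs), p=float(p),
                          n_permutations=n_perm, seed=seed, n1=n1, n2=n2)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; per-comparison p is the default)."""
    p = np.asarray(p_values, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    return adj
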