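"""Exact small-sample statistics shared by every pipeline stage.

The behavioral and neurochemical panels of the study use groups of 3-7
animals, and the network screens need hypergeometric tail probabilities far
below 1e-50.  Everything here is therefore exact (enumeration or closed
form) and computed in log-space where underflow is a risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TailProb",
    "hypergeom_upper_tail",
    "fisher_exact_2x2",
    "wilcoxon_exact",
    "bh_fdr",
    "pearson_r",
]


@dataclass(frozen=True)
class TailProb:
    """Upper-tail probability P(X >= k) of a hypergeometric draw.

    ``neglog10`` carries the tail in -log10 units so that values such as
    1e-300 and below survive; ``p`` is the same quantity clipped to the
    smallest positive float when it underflows.
    """

    p: float
    neglog10: float
    k_observed: int
    params: tuple[int, int, int]  # (N population, K successes, n draws)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> TailProb:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space.

    Infeasible ``k`` below the support returns 1, above the support returns 0.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"infeasible parameters N={N}, K={K}, n={n}")
    lo = max(0, n + K - N)
    hi = min(n, K)
    if k <= lo:
        return TailProb(1.0, 0.0, k, (N, K, n))
    if k > hi:
        return TailProb(0.0, math.inf, k, (N, K, n))
    # sf(k-1) = P(X >= k); logsf keeps tails below 1e-300 meaningful
    logp = sps.hypergeom.logsf(k - 1, N, K, n)
    p = float(np.exp(logp))
    neglog10 = float(-logp / math.log(10.0))
    return TailProb(p, neglog10, k, (N, K, n))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, point-probability method.

    Sums hypergeometric point masses (margins fixed) no larger than the
    observed table's mass — the classical two-sided exact test.  A zero row
    or column margin makes the table degenerate; p = 1 by convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def _rank_sum_distribution(ranks: np.ndarray, nx: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the x-group rank sum over all C(n, nx) splits.

    Midranks are multiples of 1/2, so doubling makes them integers and a
    subset-sum dynamic program counts every split without enumerating the
    C(n, nx) combinations explicitly.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    # table[j, s] = number of subsets of size j with doubled-rank sum s
    table = np.zeros((nx + 1, total + 1), dtype=float)
    table[0, 0] = 1.0
    for r in r2:
        table[1:, r:] += table[:-1, : total + 1 - r]
    counts_full = table[nx]
    support = np.nonzero(counts_full)[0]
    return support / 2.0, counts_full[support]


def wilcoxon_exact(x, y, exact_limit: int = 30) -> float:
    """Two-sided exact Wilcoxon rank-sum p-value with midranks for ties.

    Enumerates every split of the combined sample's (mid)ranks, so ties are
    handled exactly rather than through a variance correction.  Above
    ``exact_limit`` combined observations it falls back to the normal
    approximation with tie correction (scipy's asymptotic Mann-Whitney U).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n = x.size + y.size
    if n > exact_limit:
        return float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")[1])
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    obs = round(float(ranks[: x.size].sum()), 9)
    values, counts = _rank_sum_distribution(ranks, x.size)
    total = counts.sum()
    mean = float((values * counts).sum() / total)
    # two-sided: mass at least as far from the null mean as observed
    dev = abs(obs - mean) - 1e-9
    p = counts[np.abs(values - mean) >= dev].sum() / total
    return float(min(1.0, p))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with the t-transform p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined (degenerate)")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
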