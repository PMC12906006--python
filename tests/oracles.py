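"""Independent brute-force oracles used to validate the statistical
primitives. These deliberately avoid the library code paths (scipy /
statsmodels) that the implementation uses."""

from __future__ import annotations

import itertools
import math

import numpy as np


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top  # 1-based rank in sorted order
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return np.minimum(adj, 1.0)


def exact_rank_sum_p(x, y) -> float:
    """Two-sided rank-sum p-value by full enumeration of rank assignments
    (tie-free data only; feasible for small n+m)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "oracle requires tie-free data"
    n, m = len(x), len(y)
    ranks = np.argsort(np.argsort(pooled)) + 1
    w_obs = ranks[:n].sum()
    mean_w = n * (n + m + 1) / 2
    dev = abs(w_obs - mean_w)
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        w = sum(c + 1 for c in combo)
        total += 1
        if abs(w - mean_w) >= dev - 1e-9:
            count += 1
    return count / total


def exact_signed_rank_one_sided_p(values, alternative: str) -> float:
    """One-sided signed-rank p-value by enumerating all 2^n sign
    assignments (tie-free, nonzero values)."""
    v = np.asarray(values, float)
    assert (v != 0).all() and len(np.unique(np.abs(v))) == len(v)
    n = len(v)
    ranks = np.argsort(np.argsort(np.abs(v))) + 1
    w_obs = ranks[v > 0].sum()
    count = total = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if alternative == "less":
            count += w <= w_obs + 1e-9
        elif alternative == "greater":
            count += w >= w_obs - 1e-9
        else:
            raise ValueError(alternative)
    return count / total


def pearson_direct(a, b) -> float:
    """Pearson correlation written directly from the defining sums."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    k = len(a)
    abar, bbar = sum(a) / k, sum(b) / k
    num = sum((a[i] - abar) * (b[i] - bbar) for i in range(k))
    den = math.sqrt(sum((x - abar) ** 2 for x in a)) * math.sqrt(
        sum((x - bbar) ** 2 for x in b)
    )
    return num / den if den else float("nan")


def jaccard_brute(set_a, set_b) -> float:
    inter = len([x for x in set_a if x in set_b])
    union = len(set(list(set_a) + list(set_b)))
    return inter / union if union else float("nan")
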