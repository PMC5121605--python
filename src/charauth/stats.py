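"""Exact rank-based two-sample and paired tests.

Both tests use midranks for ties and report the conventional "smaller side"
statistic (U = min(U1, U2), W = min(W+, W-)). Exact two-sided p-values come
from the full permutation distribution:

* Mann-Whitney: enumeration of all C(n1+n2, n1) group labelings of the
  pooled values (used when n1 + n2 <= exact_limit, default 12);
* Wilcoxon signed-rank: the distribution of W+ over all 2^n sign
  assignments, computed by convolution over the (doubled, hence integer)
  midranks — identical to brute-force enumeration but O(n * total_rank_sum).

Above the exact cutoffs a normal approximation with tie correction and
continuity correction is used. The two-sided p is defined as the null
probability that the min-side statistic is at most the observed one, which
coincides with the usual doubled one-tailed value because the permutation
distributions are symmetric.
"""
from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata


def _tie_term(ranks: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 12
) -> tuple[float, float]:
    """Mann-Whitney U (min convention) with a two-sided p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    N = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    if N <= exact_limit:
        hits = 0
        total = 0
        for comb in combinations(range(N), n1):
            r1 = float(ranks[list(comb)].sum())
            u1p = r1 - n1 * (n1 + 1) / 2
            total += 1
            if min(u1p, n1 * n2 - u1p) <= u + 1e-9:
                hits += 1
        p = hits / total
    else:
        mu = n1 * n2 / 2.0
        sigma2 = n1 * n2 / 12.0 * ((N + 1) - _tie_term(ranks) / (N * (N - 1)))
        if sigma2 <= 0:
            return u, 1.0
        z = (u - mu + 0.5) / np.sqrt(sigma2)
        p = min(1.0, 2.0 * float(norm.cdf(z)))
    return u, p


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]], exact_limit: int = 25
) -> tuple[float, float]:
    """Wilcoxon signed-rank W (min of signed rank sums), two-sided p.

    Zero differences are dropped (and raise when nothing remains); tied
    absolute differences receive midranks.
    """
    diffs = np.asarray([a - b for a, b in pairs], dtype=float)
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise ValueError("all paired differences are zero")
    n = diffs.size
    ranks = rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_limit:
        # doubled midranks are integers; convolve the 2^n sign assignments
        dr = np.rint(2 * ranks).astype(int)
        t2 = int(dr.sum())
        dist = np.zeros(t2 + 1, dtype=float)
        dist[0] = 1.0
        for r in dr:
            nxt = dist.copy()
            nxt[r:] += dist[: t2 + 1 - r]
            dist = nxt
        total = 2.0**n
        w2 = int(round(2 * w))
        p = (dist[: w2 + 1].sum() + dist[t2 - w2 :].sum()) / total
        p = min(1.0, float(p))
    else:
        mu = n * (n + 1) / 4.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(ranks) / 48.0
        if sigma2 <= 0:
            return w, 1.0
        z = (w - mu + 0.5) / np.sqrt(sigma2)
        p = min(1.0, 2.0 * float(norm.cdf(z)))
    return w, p
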