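"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's embedding/pdist machinery: template
vectors are sliced per index pair and distances taken with explicit max()
over coordinates, so agreement with the package is a genuine dual-route
check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _vec(x, i, k, delay):
    return x[i : i + k * delay : delay]


def _cheb(a, b):
    return float(np.max(np.abs(a - b)))


def _match(d, r):
    return d < r if r > 0 else d == 0


def naive_pairwise_chebyshev(vectors) -> list[float]:
    vectors = np.asarray(vectors, float)
    out = []
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            out.append(_cheb(vectors[i], vectors[j]))
    return out


def naive_sampen(x, m, r_fraction, delay=1) -> float:
    x = np.asarray(x, float)
    r = r_fraction * x.std()
    count = len(x) - m * delay
    n_m = n_m1 = 0
    for i in range(count):
        for j in range(i + 1, count):
            if _match(_cheb(_vec(x, i, m, delay), _vec(x, j, m, delay)), r):
                n_m += 1
            if _match(_cheb(_vec(x, i, m + 1, delay), _vec(x, j, m + 1, delay)), r):
                n_m1 += 1
    if n_m == 0 or n_m1 == 0:
        return float("nan")
    return -math.log(n_m1 / n_m)


def naive_fuzzyen(x, m, r_fraction, n=2.0, delay=1, form="exp_dn_over_r") -> float:
    x = np.asarray(x, float)
    r = r_fraction * x.std()
    count = len(x) - m * delay

    def mem(d):
        if r == 0:
            return 1.0 if d == 0 else 0.0
        return math.exp(-(d**n) / r) if form == "exp_dn_over_r" else math.exp(-((d / r) ** n))

    def phi(k):
        tot = 0.0
        for i in range(count):
            inner = 0.0
            for j in range(count):
                if j != i:
                    inner += mem(_cheb(_vec(x, i, k, delay), _vec(x, j, k, delay)))
            tot += inner / (count - 1)
        return tot / count

    return math.log(phi(m)) - math.log(phi(m + 1))


def naive_disten(x, m, n_bins, delay=1) -> float:
    x = np.asarray(x, float)
    count = len(x) - m * delay
    dists = []
    for i in range(count):
        for j in range(i + 1, count):
            dists.append(_cheb(_vec(x, i, m, delay), _vec(x, j, m, delay)))
    lo, hi = min(dists), max(dists)
    counts = [0] * n_bins
    if hi == lo:
        counts[0] = len(dists)
    else:
        for d in dists:
            t = int((d - lo) / (hi - lo) * n_bins)
            counts[min(t, n_bins - 1)] += 1
    shen = 0.0
    for c in counts:
        if c:
            p = c / len(dists)
            shen -= p * math.log2(p)
    return shen / math.log2(n_bins)


def brute_signed_rank_p(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    ws = np.asarray(ws)
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


def brute_rank_sum_p(a, b) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    from scipy.stats import rankdata

    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    ws = [sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), n_a)]
    ws = np.asarray(ws)
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))
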