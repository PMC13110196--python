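"""Independent brute-force oracles used only by the tests.

Each function recomputes a quantity from its textbook definition with no
code shared with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def mean_oracle(x):
    vals = [v for v in x if not math.isnan(v)]
    return sum(vals) / len(vals) if vals else math.nan


def sd_oracle(x):
    vals = [v for v in x if not math.isnan(v)]
    if len(vals) < 2:
        return math.nan
    m = sum(vals) / len(vals)
    return math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))


def range_oracle(x):
    vals = [v for v in x if not math.isnan(v)]
    return max(vals) - min(vals) if vals else math.nan


def uvr_oracle(x):
    vals = [v for v in x if not math.isnan(v)]
    return len(set(vals)) / len(vals) if vals else math.nan


def autocorr_oracle(x):
    """Pearson correlation over explicitly enumerated consecutive pairs."""
    pairs = [
        (x[t], x[t + 1])
        for t in range(len(x) - 1)
        if not math.isnan(x[t]) and not math.isnan(x[t + 1])
    ]
    if len(pairs) < 2:
        return math.nan
    a = [p[0] for p in pairs]
    b = [p[1] for p in pairs]
    ma, mb = sum(a) / len(a), sum(b) / len(b)
    va = sum((v - ma) ** 2 for v in a)
    vb = sum((v - mb) ** 2 for v in b)
    if va == 0 or vb == 0:
        return math.nan
    cov = sum((p - ma) * (q - mb) for p, q in pairs)
    return cov / math.sqrt(va * vb)


def lof_oracle(X, k):
    """LOF from the reachability-distance definition, pure loops."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    d = [[math.dist(X[i], X[j]) for j in range(n)] for i in range(n)]
    neighbours = []
    kdist = []
    for i in range(n):
        others = sorted((d[i][j], j) for j in range(n) if j != i)
        neighbours.append([j for _, j in others[:k]])
        kdist.append(others[k - 1][0])
    lrd = []
    for i in range(n):
        reach = [max(kdist[j], d[i][j]) for j in neighbours[i]]
        lrd.append(1.0 / max(sum(reach) / len(reach), 1e-12))
    return np.array([
        sum(lrd[j] for j in neighbours[i]) / len(neighbours[i]) / lrd[i]
        for i in range(n)
    ])


def by_step_up_oracle(p):
    """Benjamini–Yekutieli adjustment straight from the step-up definition."""
    p = list(p)
    m = len(p)
    c_m = sum(1.0 / j for j in range(1, m + 1))
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p[i] * m * c_m / rank_from_top)
        running_min = min(running_min, value)
        adj[i] = running_min
    return np.array(adj)


def ks_d1_exact_pvalue(n, m):
    """Exact P(D = 1) for the two-sample K-S statistic: the probability that
    one sample lies entirely below the other under exchangeability."""
    return 2.0 / math.comb(n + m, n)
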