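"""Independent brute-force oracles used to check the package's statistics.

Each function here is written directly from the defining formula (or by
exhaustive enumeration) and deliberately shares no code with the package.
"""

import itertools
import math

import numpy as np


def enumeration_wilcoxon_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all C(n1+n2, n1) labelings.

    The statistic is the Mann-Whitney U of the first group; two-sided p is
    the probability, over all equally likely labelings of the pooled values,
    of a U at least as far from its null mean n1*n2/2 as the observed one.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)

    def u_stat(first, second):
        u = 0.0
        for a in first:
            for b in second:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    mid = n1 * len(y) / 2.0
    observed = abs(u_stat(x, y) - mid)
    count = 0
    total = 0
    indices = range(len(pooled))
    for subset_idx in itertools.combinations(indices, n1):
        chosen = set(subset_idx)
        first = [pooled[i] for i in subset_idx]
        second = [pooled[i] for i in indices if i not in chosen]
        total += 1
        if abs(u_stat(first, second) - mid) >= observed - 1e-12:
            count += 1
    return count / total


def welch_t(x, y):
    """Welch two-sample t statistic and Satterthwaite df from the formulas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    vx = x.var(ddof=1) / nx
    vy = y.var(ddof=1) / ny
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    return t, df


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def rank_average_ties(v):
    """Ranks 1..n with ties receiving their average rank."""
    v = list(map(float, v))
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_r(x, y) -> float:
    return pearson_r(rank_average_ties(x), rank_average_ties(y))


def quantile_linear(values, q) -> float:
    """Linear-interpolation quantile (numpy default convention), by hand."""
    v = sorted(map(float, values))
    h = (len(v) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def iqr(values) -> float:
    return quantile_linear(values, 0.75) - quantile_linear(values, 0.25)
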