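"""Independent brute-force oracles used to cross-check the statistics.

Deliberately loop-based and written from the definitions, sharing no code
with the implementation.
"""

import math

import numpy as np


def brute_stability(values):
    """Mean, CV% (n-1 sd) and MFC by explicit loops."""
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    mn, mx = min(values), max(values)
    mfc = math.inf if mn == 0 else mx / mn
    return mean, sd / mean * 100.0, mfc


def brute_median(values):
    """Middle value (odd n) or mean of two central values (even n)."""
    s = sorted(values)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2


def brute_quantile(values, level):
    """Linear-interpolation quantile of sorted values, level in [0, 100]."""
    s = sorted(values)
    if len(s) == 1:
        return s[0]
    pos = level / 100.0 * (len(s) - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(s) - 1)
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def brute_pairwise_variation(qj, qk):
    """sd (n-1) of log2 ratios, from the definition."""
    ratios = [math.log2(a / b) for a, b in zip(qj, qk)]
    mean = sum(ratios) / len(ratios)
    return math.sqrt(sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1))


def brute_m(q):
    """M(j) = mean over k != j of pairwise variation, pair enumeration."""
    genes = list(q.index)
    out = {}
    for j in genes:
        vs = [
            brute_pairwise_variation(q.loc[j].tolist(), q.loc[k].tolist())
            for k in genes
            if k != j
        ]
        out[j] = sum(vs) / len(vs)
    return out


def brute_spearman(x, y):
    """Pearson correlation of hand-computed average ranks."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den
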