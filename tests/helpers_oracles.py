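"""Independent brute-force oracles for the statistics core.

Plain-Python implementations kept deliberately separate from the package's
vectorised ones: explicit rank arithmetic, ECDF enumeration, direct formula
evaluation.
"""

from collections import defaultdict


def average_ranks_oracle(values):
    srt = sorted(values)
    pos = defaultdict(list)
    for i, v in enumerate(srt):
        pos[v].append(i + 1)
    rank_of = {v: sum(ps) / len(ps) for v, ps in pos.items()}
    return [rank_of[v] for v in values], pos


def kruskal_wallis_oracle(groups):
    """H with tie correction via the explicit rank-sum formula."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    _, pos = average_ranks_oracle(pooled)
    rank_of = {v: sum(ps) / len(ps) for v, ps in pos.items()}
    h = 0.0
    for g in groups:
        rsum = sum(rank_of[x] for x in g)
        h += rsum * rsum / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    ties = sum(len(ps) ** 3 - len(ps) for ps in pos.values())
    denom = 1.0 - ties / (n ** 3 - n)
    return h / denom if denom > 0 else 0.0


def pearson_oracle(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def ks_statistic_oracle(x, y):
    """sup |ECDF_x - ECDF_y| by enumerating every threshold."""
    d = 0.0
    for t in list(x) + list(y):
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        d = max(d, abs(fx - fy))
    return d


def kolmogorov_sf_oracle(lam, terms=100):
    """Asymptotic Kolmogorov survival function by direct series evaluation."""
    if lam <= 0:
        return 1.0
    import math
    s = 0.0
    for k in range(1, terms + 1):
        s += (-1) ** (k - 1) * math.exp(-2.0 * k * k * lam * lam)
    return min(1.0, max(0.0, 2.0 * s))


def sidak_oracle(p, m):
    return min(1.0, 1.0 - (1.0 - p) ** m)


def ols_oracle(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    slope = sxy / sxx
    return slope, my - slope * mx


def percentile_oracle(values, q):
    """Linear-interpolation percentile between order statistics."""
    srt = sorted(values)
    n = len(srt)
    h = (n - 1) * q / 100.0
    lo = int(h)
    if lo >= n - 1:
        return float(srt[-1])
    frac = h - lo
    return srt[lo] + frac * (srt[lo + 1] - srt[lo])
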