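"""Independent brute-force oracles used by the tests.

Everything here is written with explicit loops and elementary arithmetic,
independent of the package's vectorized implementations, so that agreement
between the two routes is meaningful.
"""

import math

import numpy as np


def average_ranks(values):
    """Average ranks (1-based) with ties sharing the mean tied position."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def trim_keep(values, trim):
    """Indices kept by a two-sided trim of ``trim`` per tail by average rank."""
    n = len(values)
    lo = math.floor(n * trim) + 1
    hi = n + 1 - lo
    ranks = average_ranks(values)
    return [i for i in range(n) if lo <= ranks[i] <= hi]


def tmm_log2_factor(counts, j, r, trim_M=0.30, trim_A=0.05):
    """Direct evaluation of the trimmed weighted mean of M-values for sample j
    against reference r."""
    G, m = counts.shape
    N = [sum(counts[g][s] for g in range(G)) for s in range(m)]
    Ms, As, vs = [], [], []
    for g in range(G):
        kj, kr = counts[g][j], counts[g][r]
        if kj > 0 and kr > 0:
            Ms.append(math.log2((kj / N[j]) / (kr / N[r])))
            As.append(0.5 * (math.log2(kj / N[j]) + math.log2(kr / N[r])))
            vs.append((N[j] - kj) / (N[j] * kj) + (N[r] - kr) / (N[r] * kr))
    keep_m = set(trim_keep(Ms, trim_M))
    keep_a = set(trim_keep(As, trim_A))
    keep = sorted(keep_m & keep_a)
    num = sum(Ms[i] / vs[i] for i in keep)
    den = sum(1.0 / vs[i] for i in keep)
    return num / den if den else 0.0


def median_ratio_factor(counts, j):
    """Direct evaluation of the median of ratios to the per-gene geometric mean."""
    G, m = counts.shape
    ratios = []
    for g in range(G):
        if all(counts[g][v] > 0 for v in range(m)):
            geo = math.exp(sum(math.log(counts[g][v]) for v in range(m)) / m)
            ratios.append(counts[g][j] / geo)
    return float(np.median(ratios))


def quantile_factor(counts, j):
    """Direct evaluation of the centred upper-quartile depth factor."""
    G, m = counts.shape
    logq = [math.log10(np.percentile(counts[:, v], 75)) for v in range(m)]
    return 10.0 ** (logq[j] - sum(logq) / m)


def poissonseq_factors(counts):
    """Direct evaluation of the one-pass goodness-of-fit depth estimate."""
    G, m = counts.shape
    N = [sum(counts[g][j] for g in range(G)) for j in range(m)]
    total = sum(N)
    tc = [N[j] / total for j in range(m)]
    gofs = {}
    for g in range(G):
        S = sum(counts[g])
        if S == 0:
            continue
        gofs[g] = sum(
            (counts[g][j] - tc[j] * S) ** 2 / (tc[j] * S) for j in range(m)
        )
    vals = list(gofs.values())
    qlo, qhi = np.quantile(vals, 0.25), np.quantile(vals, 0.75)
    selected = [g for g, v in gofs.items() if qlo <= v <= qhi]
    denom = sum(counts[g][j] for g in selected for j in range(m))
    return [sum(counts[g][j] for g in selected) / denom for j in range(m)], selected


def bh_adjust(pvalues):
    """Hand-stepped Benjamini-Hochberg step-up adjustment."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        value = min(prev, pvalues[i] * n / rank_from_top)
        adjusted[i] = value
        prev = value
    return adjusted


def binomial_two_sided_p(s1, total, prob):
    """Two-sided exact binomial p: total probability of outcomes no more
    likely than the observed count."""
    from scipy.stats import binom

    pmf = [binom.pmf(k, total, prob) for k in range(total + 1)]
    obs = pmf[s1]
    return min(1.0, sum(p for p in pmf if p <= obs * (1 + 1e-9)))
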