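"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written from first principles (pure
Python loops, explicit enumeration, hand-rolled rank/quantile rules) and
must stay independent of the package implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math


def quantile_linear(values, p):
    """Linear interpolation between order statistics at 1 + (n-1)p (1-based)."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return float(xs[0])
    pos = (n - 1) * p  # 0-based
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return xs[lo] + frac * (xs[hi] - xs[lo])


def agreement_brute(egfr, sgfr):
    """Field-by-field recomputation of the agreement summary."""
    d = [e - s for e, s in zip(egfr, sgfr)]
    ad = [abs(x) for x in d]
    rel = [abs(e - s) / s for e, s in zip(egfr, sgfr)]
    n = len(d)
    counts = {tol: sum(1 for r in rel if r < tol) for tol in (0.15, 0.30, 0.50)}
    return {
        "n": n,
        "median_diff": quantile_linear(d, 0.5),
        "diff_iqr": (quantile_linear(d, 0.25), quantile_linear(d, 0.75)),
        "median_abs_diff": quantile_linear(ad, 0.5),
        "abs_diff_iqr": (quantile_linear(ad, 0.25), quantile_linear(ad, 0.75)),
        "p15_count": counts[0.15],
        "p30_count": counts[0.30],
        "p50_count": counts[0.50],
        "p15_pct": 100.0 * counts[0.15] / n,
        "p30_pct": 100.0 * counts[0.30] / n,
        "p50_pct": 100.0 * counts[0.50] / n,
    }


def bland_altman_brute(egfr, sgfr):
    d = [e - s for e, s in zip(egfr, sgfr)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    sd = math.sqrt(var)
    return {
        "mean_diff": mean,
        "sd_diff": sd,
        "loa_low": mean - 1.96 * sd,
        "loa_high": mean + 1.96 * sd,
        "loa_width": 3.92 * sd,
    }


def average_ranks(values):
    """Hand-rolled midrank computation."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def wilcoxon_exact_brute(d):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = [x for x in d if x != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = average_ranks([abs(x) for x in d])
    w_obs = sum(r for x, r in zip(d, ranks) if x > 0)
    sums = []
    for signs in itertools.product([0, 1], repeat=n):
        sums.append(sum(r for s, r in zip(signs, ranks) if s))
    total = len(sums)
    lo = sum(1 for w in sums if w <= w_obs + 1e-12) / total
    hi = sum(1 for w in sums if w >= w_obs - 1e-12) / total
    return w_obs, min(1.0, 2.0 * min(lo, hi))


def mann_whitney_exact_brute(x, y):
    """Exact two-sided rank-sum p by enumerating group assignments."""
    nx = len(x)
    pooled = list(x) + list(y)
    ranks = average_ranks(pooled)
    u_obs = sum(ranks[:nx]) - nx * (nx + 1) / 2.0
    stats = []
    for combo in itertools.combinations(range(len(pooled)), nx):
        u = sum(ranks[i] for i in combo) - nx * (nx + 1) / 2.0
        stats.append(u)
    total = len(stats)
    lo = sum(1 for u in stats if u <= u_obs + 1e-12) / total
    hi = sum(1 for u in stats if u >= u_obs - 1e-12) / total
    return u_obs, min(1.0, 2.0 * min(lo, hi))


def kruskal_wallis_h_brute(groups):
    """H statistic with tie correction, from scratch."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = average_ranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start : start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    tie_counts = {}
    for v in pooled:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    correction = 1.0 - sum(t ** 3 - t for t in tie_counts.values()) / (n ** 3 - n)
    return h / correction


def mcnemar_exact_brute(b, c):
    """Exact two-sided binomial p from the discordant counts."""
    m = b + c
    if m == 0:
        return 1.0
    k = min(b, c)
    cdf = sum(math.comb(m, i) for i in range(k + 1)) / 2.0 ** m
    return min(1.0, 2.0 * cdf)


def pearson_chi2_brute(table):
    """Pearson statistic from brute-force expected counts."""
    rows = len(table)
    cols = len(table[0])
    total = sum(sum(r) for r in table)
    row_sums = [sum(r) for r in table]
    col_sums = [sum(table[i][j] for i in range(rows)) for j in range(cols)]
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            expected = row_sums[i] * col_sums[j] / total
            stat += (table[i][j] - expected) ** 2 / expected
    return stat, (rows - 1) * (cols - 1)


def rbf_minnorm_brute(x, y, spread):
    """Minimum-norm least-squares fit of the bias-augmented Gaussian design,
    via an explicitly coded SVD pseudoinverse (numpy only for the SVD)."""
    import numpy as np

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    phi = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d = 0.8326 * abs(x[i] - x[j]) / spread
            phi[i, j] = math.exp(-(d * d))
    a = np.hstack([phi, np.ones((n, 1))])
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    cutoff = max(a.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    s_inv = np.array([1.0 / sv if sv > cutoff else 0.0 for sv in s])
    theta = vt.T @ (s_inv * (u.T @ y))
    return theta[:-1], float(theta[-1])


def rbf_forward_brute(centers, weights, bias, spread, x):
    """Scalar forward pass from first principles."""
    total = bias
    for c, w in zip(centers, weights):
        d = 0.8326 * abs(x - c) / spread
        total += w * math.exp(-(d * d))
    return total
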