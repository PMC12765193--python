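"""Independent brute-force oracles used to check the statistical primitives.

Deliberately naive implementations: exact integer combinatorics for the
hypergeometric tail and a literal step-up loop for Benjamini-Hochberg, kept
free of scipy/statsmodels so they provide a second route.
"""

import math

import numpy as np


def bh_stepup_oracle(p):
    """Literal BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, clipped to 1."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return np.array(q)


def hypergeom_pmf_exact(k, n_total, size_a, size_b):
    """P(overlap == k) for two fixed-size subsets of an n_total universe."""
    denom = math.comb(n_total, size_b)
    if denom == 0:
        return 0.0
    return math.comb(size_a, k) * math.comb(n_total - size_a, size_b - k) / denom


def fisher_p_oracle(k, size_a, size_b, n_total, sidedness="two_sided"):
    """Exact Fisher p by summing hypergeometric point masses.

    Two-sided: sum of all point masses <= the observed mass (with a tiny
    relative tolerance for float comparison); greater: upper tail.
    """
    lo = max(0, size_a + size_b - n_total)
    hi = min(size_a, size_b)
    pmf = {i: hypergeom_pmf_exact(i, n_total, size_a, size_b) for i in range(lo, hi + 1)}
    if sidedness == "greater":
        return min(1.0, sum(pmf[i] for i in range(k, hi + 1)))
    observed = pmf[k]
    total = sum(v for v in pmf.values() if v <= observed * (1 + 1e-12))
    return min(1.0, total)


def pearson_r_oracle(x, y):
    """Covariance over product of SDs, written out longhand."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def welch_p_oracle(a, b):
    """Welch two-sided p from the textbook statistic and df formula."""
    from scipy.stats import t as tdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * tdist.sf(abs(t), df)


def bfs_distances(adjacency, start):
    """Plain breadth-first search distances over an adjacency dict."""
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for node in frontier:
            for nb in adjacency.get(node, ()):
                if nb not in dist:
                    dist[nb] = dist[node] + 1
                    nxt.append(nb)
        frontier = nxt
    return dist
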