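"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations straight from the definitions —
neighbour-pair enumeration, Floyd-Warshall, summed trapezoids, textbook
t-statistics — kept free of any code under test.
"""

import math

import numpy as np


def pearson_brute(x, y):
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def floyd_warshall(adj):
    n = len(adj)
    d = [[0.0 if i == j else (1.0 if adj[i][j] else math.inf) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return np.array(d)


def clustering_brute(adj, i):
    nb = [j for j in range(len(adj)) if adj[i][j]]
    k = len(nb)
    if k < 2:
        return 0.0
    links = sum(1 for a in range(k) for b in range(a + 1, k) if adj[nb[a]][nb[b]])
    return links / (k * (k - 1) / 2)


def lp_brute(adj):
    """(mean finite off-diagonal distance, unreachable unordered pair count)."""
    d = floyd_warshall(adj)
    n = len(adj)
    finite, infinite = [], 0
    for i in range(n):
        for j in range(i + 1, n):
            if math.isinf(d[i][j]):
                infinite += 1
            else:
                finite.append(d[i][j])
    return sum(finite) / len(finite), infinite


def global_eff_brute(adj):
    d = floyd_warshall(adj)
    n = len(adj)
    if n < 2:
        return 0.0
    total = sum(
        0.0 if math.isinf(d[i][j]) else 1.0 / d[i][j]
        for i in range(n) for j in range(n) if i != j
    )
    return total / (n * (n - 1))


def local_eff_brute(adj, i):
    nb = [j for j in range(len(adj)) if adj[i][j]]
    if len(nb) < 2:
        return 0.0
    sub = [[adj[a][b] for b in nb] for a in nb]
    return global_eff_brute(sub)


def trapezoid_brute(xs, ys):
    total = 0.0
    for k in range(len(xs) - 1):
        total += (xs[k + 1] - xs[k]) * (ys[k] + ys[k + 1]) / 2.0
    return total


def pooled_t_brute(x, y):
    """Textbook pooled-variance two-sample t and its df."""
    n1, n2 = len(x), len(y)
    m1, m2 = sum(x) / n1, sum(y) / n2
    v1 = sum((a - m1) ** 2 for a in x) / (n1 - 1)
    v2 = sum((b - m2) ** 2 for b in y) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, n1 + n2 - 2


def bh_brute(ps):
    """Benjamini-Hochberg step-up adjusted p-values by direct definition."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, ps[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj


def random_graph(n, p, rng):
    adj = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i, j] = adj[j, i] = 1
    return adj
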