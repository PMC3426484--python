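"""Independent oracle implementations used by the test suite.

These are deliberately naive (direct transcriptions of definitions,
enumeration, exact summation) and share no code with the package.
"""

import itertools
import math

import numpy as np


def wc_theta_haploid(n1, d1, n2, d2):
    """Weir-Cockerham two-population theta-hat for haploid counts, written
    as the a / (a + b) variance components (r = 2)."""
    r = 2
    p1, p2 = d1 / n1, d2 / n2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / ((n1 - 1) + (n2 - 1))
    a = (msp - msg) / nc
    b = msg
    if a + b == 0:
        return float("nan")
    return a / (a + b)


def ehh_pairwise(H, carriers, core, j):
    """EHH as the probability two random distinct carriers are identical
    over the span core..j (O(n^2 m) pairwise comparison)."""
    lo, hi = min(core, j), max(core, j)
    n = len(carriers)
    same = 0
    for a, b in itertools.combinations(carriers, 2):
        if np.array_equal(H[a, lo : hi + 1], H[b, lo : hi + 1]):
            same += 1
    return same / (n * (n - 1) // 2)


def chi2_upper_tail_even_df(z, k):
    """Exact chi-squared upper tail for 2k degrees of freedom:
    exp(-z/2) * sum_{i<k} (z/2)^i / i!."""
    half = z / 2.0
    return math.exp(-half) * sum(half**i / math.factorial(i) for i in range(k))


def empirical_p_direct(scores, value):
    """(# strictly greater + 1) / (n + 1) by direct counting."""
    greater = sum(1 for s in scores if s > value)
    return (greater + 1) / (len(scores) + 1)


def chi2_goodness_direct(n_genes, observed):
    """Sum (O - E)^2 / E with E proportional to part gene counts."""
    total = sum(observed)
    chi2 = 0.0
    for n, o in zip(n_genes, observed):
        e = n * total / sum(n_genes)
        chi2 += (o - e) ** 2 / e
    return chi2


def hypergeom_p_under(M, K, n, k):
    """P[X <= k] for X ~ Hypergeom(M, K, n) by exact summation."""
    total = math.comb(M, n)
    return sum(
        math.comb(K, i) * math.comb(M - K, n - i) / total
        for i in range(0, k + 1)
        if n - i <= M - K
    )


# --- graph centralities by brute force -------------------------------------


def floyd_warshall(adj):
    n = len(adj)
    D = [[0 if i == j else (1 if adj[i][j] else math.inf) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i][k] + D[k][j] < D[i][j]:
                    D[i][j] = D[i][k] + D[k][j]
    return D


def _all_shortest_paths(adj, D, s, t):
    """Enumerate all shortest s-t paths by DFS along distance-decreasing edges."""
    if D[s][t] == math.inf:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in range(len(adj)):
            if adj[u][v] and D[u][t] == D[v][t] + 1:
                extend(path + [v])

    extend([s])
    return paths


def brute_force_centralities(adj):
    """degree, reciprocal eccentricity/closeness, betweenness (unordered
    pairs, endpoints excluded), centroid -- all straight from definitions."""
    n = len(adj)
    D = floyd_warshall(adj)
    degree = [sum(adj[i]) for i in range(n)]
    ecc = []
    clo = []
    for i in range(n):
        ds = [D[i][j] for j in range(n) if j != i and D[i][j] < math.inf]
        ecc.append(1.0 / max(ds) if ds else math.nan)
        clo.append(1.0 / sum(ds) if ds else math.nan)
    btw = [0.0] * n
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, D, s, t)
            if not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                btw[v] += through / len(paths)
    centroid = []
    for v in range(n):
        comp = [u for u in range(n) if D[v][u] < math.inf]
        others = [w for w in comp if w != v]
        if not others:
            centroid.append(math.nan)
            continue
        vals = []
        for w in others:
            gamma_vw = sum(1 for u in comp if D[u][v] < D[u][w])
            gamma_wv = sum(1 for u in comp if D[u][w] < D[u][v])
            vals.append(gamma_vw - gamma_wv)
        centroid.append(min(vals))
    return {
        "degree": degree,
        "eccentricity_c": ecc,
        "closeness_c": clo,
        "betweenness": btw,
        "centroid": centroid,
    }
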