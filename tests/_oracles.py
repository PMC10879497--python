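"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (Floyd-Warshall, explicit path
enumeration, exhaustive partition search, step-up by hand) and shares no
code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    D = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def cpl(A: np.ndarray) -> float:
    D = floyd_warshall(A)
    n = A.shape[0]
    vals = [D[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(D[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def clustering_per_node(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if A[i, j]]
        k = len(nb)
        if k < 2:
            continue
        tri = sum(A[u, v] for u, v in itertools.combinations(nb, 2))
        out[i] = 2.0 * tri / (k * (k - 1))
    return out


def average_clustering(A: np.ndarray) -> float:
    return float(clustering_per_node(A).mean())


def local_efficiency(A: np.ndarray) -> float:
    n = A.shape[0]
    effs = []
    for i in range(n):
        nb = [j for j in range(n) if A[i, j]]
        m = len(nb)
        if m < 2:
            effs.append(0.0)
            continue
        sub = A[np.ix_(nb, nb)]
        D = floyd_warshall(sub)
        s = sum(1.0 / D[u, v] for u in range(m) for v in range(m)
                if u != v and np.isfinite(D[u, v]))
        effs.append(s / (m * (m - 1)))
    return float(np.mean(effs))


def nodal_efficiency(A: np.ndarray) -> np.ndarray:
    D = floyd_warshall(A)
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        s = sum(1.0 / D[i, j] for j in range(n)
                if j != i and np.isfinite(D[i, j]) and D[i, j] > 0)
        out[i] = s / (n - 1)
    return out


def assortativity(A: np.ndarray) -> float:
    deg = A.sum(axis=1)
    xs, ys = [], []
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if A[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def betweenness(A: np.ndarray) -> np.ndarray:
    """Unnormalised, endpoints excluded; by explicit enumeration of all
    shortest paths per unordered pair."""
    n = A.shape[0]
    D = floyd_warshall(A)
    out = np.zeros(n)

    def paths(s, t):
        # all shortest s->t paths, following strictly distance-decreasing edges
        if s == t:
            return [[t]]
        acc = []
        for v in range(n):
            if A[s, v] and np.isfinite(D[v, t]) and D[v, t] == D[s, t] - 1:
                for rest in paths(v, t):
                    acc.append([s] + rest)
        return acc

    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(D[s, t]):
                continue
            ps = paths(s, t)
            if not ps:
                continue
            for p in ps:
                for v in p[1:-1]:
                    out[v] += 1.0 / len(ps)
    return out


def partitions_of(n: int):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    def rec(prefix, k):
        i = len(prefix)
        if i == n:
            yield np.array(prefix)
            return
        for c in range(k + 1):
            yield from rec(prefix + [c], max(k, c + 1))
    yield from rec([0], 1)


def modularity_q(A: np.ndarray, labels: np.ndarray) -> float:
    """Newman-Girvan Q via the e_cc - a_c^2 formulation (gamma = 1)."""
    twom = A.sum()
    if twom == 0:
        return 0.0
    deg = A.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        e = A[np.ix_(idx, idx)].sum() / twom
        a = deg[idx].sum() / twom
        q += e - a * a
    return float(q)


def max_modularity(A: np.ndarray) -> float:
    return max(modularity_q(A, lab) for lab in partitions_of(A.shape[0]))


def bh_stepup(p: np.ndarray, alpha: float = 0.05):
    """Benjamini-Hochberg by the textbook step-up definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    thresh = alpha * np.arange(1, m + 1) / m
    below = np.nonzero(ps <= thresh)[0]
    k = below.max() + 1 if below.size else 0
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    q_sorted = np.minimum.accumulate((ps * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return reject, q


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """sup |ECDF_a - ECDF_b| over the pooled sample points."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    grid = np.concatenate([a, b])
    best = 0.0
    for x in grid:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return float(best)
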