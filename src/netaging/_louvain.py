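"""Numba kernels for resolution-parametrised Louvain community detection.

All kernels operate on dense symmetric non-negative weight matrices. The
quality function is the resolution-adjusted Newman-Girvan modularity

    Q(gamma) = (1/2m) * sum_ij [ W_ij - gamma * k_i k_j / (2m) ] * delta(c_i, c_j)

with 2m = sum of all matrix entries (aggregated graphs carry the full
double-counted internal weight on their diagonal, which keeps Q invariant
under aggregation).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def q_value(W: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """Resolution-adjusted modularity of a labelling of W."""
    n = W.shape[0]
    twom = 0.0
    k = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            s += W[i, j]
        k[i] = s
        twom += s
    if twom <= 0.0:
        return 0.0
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += W[i, j] - gamma * k[i] * k[j] / twom
    return q / twom


@njit(cache=True)
def local_move(W: np.ndarray, gamma: float, labels: np.ndarray,
               order: np.ndarray) -> bool:
    """Greedy single-node moves until no move improves Q. Mutates ``labels``.

    Community ids live in 0..n-1; emptied ids may be re-used for nodes that
    profit from splitting off into a singleton (relevant at high gamma).
    Ties keep the current community (first strictly better candidate wins,
    scanned in ascending community id for determinism given ``order``).
    """
    n = W.shape[0]
    k = np.zeros(n)
    twom = 0.0
    for i in range(n):
        s = 0.0
        for j in range(n):
            s += W[i, j]
        k[i] = s
        twom += s
    if twom <= 0.0:
        return False

    sigma = np.zeros(n)   # total degree per community id
    count = np.zeros(n, dtype=np.int64)
    for i in range(n):
        sigma[labels[i]] += k[i]
        count[labels[i]] += 1

    tol = 1e-12
    improved = False
    moved = True
    while moved:
        moved = False
        for t in range(n):
            i = order[t]
            a = labels[i]
            # weight from i to each community (self-loop excluded; it stays
            # internal whatever the assignment and cancels in comparisons)
            wc = np.zeros(n)
            for j in range(n):
                if j != i:
                    w = W[i, j]
                    if w != 0.0:
                        wc[labels[j]] += w
            sigma[a] -= k[i]
            count[a] -= 1
            stay = wc[a] - gamma * k[i] * sigma[a] / twom
            best = a
            best_score = stay
            # candidate: fresh singleton community (score 0)
            if 0.0 > best_score + tol:
                for c in range(n):
                    if count[c] == 0:
                        best = c
                        best_score = 0.0
                        break
            for c in range(n):
                if wc[c] > 0.0 and c != a:
                    score = wc[c] - gamma * k[i] * sigma[c] / twom
                    if score > best_score + tol:
                        best = c
                        best_score = score
            labels[i] = best
            sigma[best] += k[i]
            count[best] += 1
            if best != a:
                moved = True
                improved = True
    return improved


@njit(cache=True)
def aggregate(W: np.ndarray, comp: np.ndarray, nc: int) -> np.ndarray:
    """Collapse communities into super-nodes; diagonal keeps the full
    double-counted internal weight so row sums remain community degrees."""
    n = W.shape[0]
    out = np.zeros((nc, nc))
    for i in range(n):
        ci = comp[i]
        for j in range(n):
            out[ci, comp[j]] += W[i, j]
    return out
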