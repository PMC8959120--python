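"""Numba-compiled inner loops.

The experiment driver runs millions of map updates per model; these kernels
use edge-list neighbor sums (O(m) per update instead of the dense O(n^2)
matrix-vector product) and fuse the update/rewire cycle so long simulations
stay fast on a single core.  The pure-numpy operations in ``dynamics`` and
``rewiring`` remain the reference semantics; the kernel is cross-checked
against them in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by run_attempts
OK = 0
NO_NON_NEIGHBOR = 1
ISOLATED_NODE = 2


@njit(cache=True)
def run_attempts(A, eu, ev, deg, x, c1, c2, inv_deg, acc_alpha, alpha, pivots, k_updates):
    """Advance the model by up to ``len(pivots)`` rewiring attempts.

    Each attempt is ``k_updates`` coupled-map updates followed by one
    rewiring.  Update rule (per node): x <- 1 - c1*x^2 - c2*s/deg where
    s accumulates neighbors' x_j^2 (acc_alpha == 0) or alpha_j*x_j^2
    (acc_alpha == 1); c1/c2 encode the amplitude convention.

    Arrays A (dense adjacency), eu/ev (edge endpoints), deg, inv_deg and x
    are updated in place.  Returns (status, attempts_done, node) where node
    is the offending node for a pathological status (-1 otherwise).
    """
    n = A.shape[0]
    m = eu.shape[0]
    x2 = np.empty(n)
    s = np.empty(n)
    n_attempts = pivots.shape[0]
    for a in range(n_attempts):
        for i in range(n):
            if deg[i] == 0.0:
                return ISOLATED_NODE, a, i
        for _ in range(k_updates):
            if acc_alpha == 0:
                for i in range(n):
                    x2[i] = x[i] * x[i]
                    s[i] = 0.0
            else:
                for i in range(n):
                    x2[i] = alpha[i] * x[i] * x[i]
                    s[i] = 0.0
            for e in range(m):
                u = eu[e]
                v = ev[e]
                s[u] += x2[v]
                s[v] += x2[u]
            if acc_alpha == 0:
                for i in range(n):
                    x[i] = 1.0 - c1[i] * x2[i] - c2[i] * s[i] * inv_deg[i]
            else:
                for i in range(n):
                    x[i] = 1.0 - c1[i] * x[i] * x[i] - c2[i] * s[i] * inv_deg[i]
        piv = pivots[a]
        xp = x[piv]
        best_d = -1.0
        xi = -1
        best_s = -2.0
        zeta = -1
        for j in range(n):
            if j == piv:
                continue
            dj = abs(x[j] - xp)
            if A[piv, j] == 1.0:
                if dj > best_d:
                    best_d = dj
                    xi = j
            else:
                sj = 1.0 - dj
                if sj > best_s:
                    best_s = sj
                    zeta = j
        if xi == -1:
            return ISOLATED_NODE, a, piv
        if zeta == -1:
            return NO_NON_NEIGHBOR, a, piv
        A[piv, xi] = 0.0
        A[xi, piv] = 0.0
        A[piv, zeta] = 1.0
        A[zeta, piv] = 1.0
        deg[xi] -= 1.0
        deg[zeta] += 1.0
        inv_deg[xi] = 1.0 / deg[xi] if deg[xi] > 0.0 else 0.0
        inv_deg[zeta] = 1.0 / deg[zeta]
        for e in range(m):
            if (eu[e] == piv and ev[e] == xi) or (eu[e] == xi and ev[e] == piv):
                if piv < zeta:
                    eu[e] = piv
                    ev[e] = zeta
                else:
                    eu[e] = zeta
                    ev[e] = piv
                break
    return OK, n_attempts, -1


@njit(cache=True)
def double_edge_swaps(A, eu, ev, pair_idx, orient):
    """Degree-preserving randomization by repeated double-edge swaps.

    ``pair_idx`` is a (k, 2) array of candidate edge-index pairs and
    ``orient`` a length-k 0/1 array choosing the reconnection pattern.
    Swaps creating self-loops or multi-edges are rejected.  A, eu, ev are
    modified in place; returns the number of accepted swaps.
    """
    accepted = 0
    for t in range(pair_idx.shape[0]):
        e1 = pair_idx[t, 0]
        e2 = pair_idx[t, 1]
        if e1 == e2:
            continue
        a = eu[e1]
        b = ev[e1]
        c = eu[e2]
        d = ev[e2]
        if orient[t] == 1:
            c, d = d, c
        # propose (a, c) and (b, d)
        if a == c or b == d:
            continue
        if A[a, c] == 1.0 or A[b, d] == 1.0:
            continue
        A[a, b] = 0.0
        A[b, a] = 0.0
        A[c, d] = 0.0
        A[d, c] = 0.0
        A[a, c] = 1.0
        A[c, a] = 1.0
        A[b, d] = 1.0
        A[d, b] = 1.0
        eu[e1] = a
        ev[e1] = c
        eu[e2] = b
        ev[e2] = d
        accepted += 1
    return accepted


@njit(cache=True)
def hhg_statistic(Dx, Dy):
    """Heller-Heller-Gorfine test statistic from two distance matrices.

    For every ordered pair (i, j), the remaining points are cross-classified
    by whether they fall inside the balls of radius Dx[i, j] around i in X
    and Dy[i, j] around i in Y (strict inequalities); the statistic sums the
    Pearson chi-square of the resulting 2x2 tables.
    """
    n = Dx.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rx = Dx[i, j]
            ry = Dy[i, j]
            a11 = 0
            a12 = 0
            a21 = 0
            a22 = 0
            for k in range(n):
                if k == i or k == j:
                    continue
                inx = Dx[i, k] < rx
                iny = Dy[i, k] < ry
                if inx and iny:
                    a11 += 1
                elif inx:
                    a12 += 1
                elif iny:
                    a21 += 1
                else:
                    a22 += 1
            r1 = a11 + a12
            r2 = a21 + a22
            c1 = a11 + a21
            c2 = a12 + a22
            denom = r1 * r2 * c1 * c2
            if denom > 0:
                diff = a12 * a21 - a11 * a22
                total += (n - 2) * (diff * diff) / denom
    return total
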