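"""Independent test oracles, deliberately naive.

These re-derive revealed-preference results by exhaustive enumeration so the
production engine (boolean-closure based) can be checked against a second,
structurally different route.  They are slow by design and only used at tiny
problem sizes.
"""

from __future__ import annotations

import numpy as np


def direct_relations(prices: np.ndarray, bundles: np.ndarray, tol: float = 1e-8):
    """R0/P0 by definition, one pair at a time."""
    K = prices.shape[0]
    R0 = np.zeros((K, K), dtype=bool)
    P0 = np.zeros((K, K), dtype=bool)
    for i in range(K):
        e_i = float(prices[i] @ bundles[i])
        for j in range(K):
            c_ij = float(prices[i] @ bundles[j])
            R0[i, j] = e_i >= c_ij - tol * e_i
            P0[i, j] = e_i > c_ij + tol * e_i
    return R0, P0


def brute_force_violations(prices, bundles, tol: float = 1e-8):
    """GARP violations by enumerating every revealed-preference path.

    x_i is revealed (possibly indirectly) preferred to x_j when some
    sequence of budgets i -> ... -> j is linked head-to-tail by R0.  All
    simple paths are enumerated by depth-first search; a violation is a pair
    with such a path i ~> j and P0[j, i], direct when the single edge
    R0[i, j] already exists.

    Returns a set of (i, j, kind) triples.
    """
    K = prices.shape[0]
    R0, P0 = direct_relations(prices, bundles, tol)
    reachable = np.zeros((K, K), dtype=bool)
    for start in range(K):
        stack = [(start, {start})]
        while stack:
            node, seen = stack.pop()
            for nxt in range(K):
                if R0[node, nxt] and nxt not in seen:
                    reachable[start, nxt] = True
                    stack.append((nxt, seen | {nxt}))
        reachable[start, start] = True
    out = set()
    for i in range(K):
        for j in range(K):
            if i != j and reachable[i, j] and P0[j, i]:
                out.add((i, j, "direct" if R0[i, j] else "indirect"))
    return out


def ccei_grid_scan(prices, bundles, grid: int = 20001) -> float:
    """Afriat efficiency index by brute-force scan of e over a fine grid."""
    K = prices.shape[0]
    best = 0.0
    for e in np.linspace(0.0, 1.0, grid):
        R0 = np.zeros((K, K), dtype=bool)
        P0 = np.zeros((K, K), dtype=bool)
        for i in range(K):
            e_i = float(prices[i] @ bundles[i])
            for j in range(K):
                c_ij = float(prices[i] @ bundles[j])
                R0[i, j] = e * e_i >= c_ij
                P0[i, j] = e * e_i > c_ij
        # reachability via repeated multiplication
        R = R0 | np.eye(K, dtype=bool)
        for _ in range(K):
            R = R | (R @ R)
        ok = True
        for i in range(K):
            for j in range(K):
                if i != j and R[i, j] and P0[j, i]:
                    ok = False
        if ok:
            best = float(e)
    return best


def grid_max_utility_share(utility, d_H: float, d_M: float, n_grid: int = 10001):
    """Share maximizing a utility over an n_grid discretization of a budget line."""
    f = np.linspace(0.0, 1.0, n_grid)
    u = utility(f * d_H, (1.0 - f) * d_M)
    return float(f[np.argmax(u)]), float(np.max(u))
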