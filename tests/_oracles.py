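"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles (or from a
different library routine) than the code under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from sklearn.tree import DecisionTreeClassifier


def textbook_adaboost(X, y, n_rounds, max_depth=2, tree_seeds=None):
    """Plain-loop discrete AdaBoost; returns (trees, alphas).

    Follows the blackboard formulation: D_1 = 1/m; eps = sum of D over
    misclassified; alpha = 0.5 ln((1-eps)/eps); D_i <- D_i * exp(-alpha
    y_i h(x_i)) with labels in {-1, +1}; renormalize.  Stops early on a
    perfect round.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y, dtype=int)
    ypm = 2 * y01 - 1
    m = len(y01)
    D = np.ones(m) / m
    trees, alphas = [], []
    for r in range(n_rounds):
        seed = None if tree_seeds is None else tree_seeds[r]
        tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
        tree.fit(X, y01, sample_weight=D * m)
        hpm = 2 * tree.predict(X) - 1
        eps = float(D[hpm != ypm].sum())
        if eps >= 0.5:
            break
        eps_c = min(max(eps, 1e-10), 1 - 1e-10)
        alpha = 0.5 * math.log((1 - eps_c) / eps_c)
        trees.append(tree)
        alphas.append(alpha)
        if eps == 0.0:
            break
        D = D * np.exp(-alpha * ypm * hpm)
        D = D / D.sum()
    return trees, alphas


def adaboost_margins(trees, alphas, X):
    X = np.asarray(X, dtype=float)
    out = np.zeros(len(X))
    for tree, alpha in zip(trees, alphas):
        out += alpha * (2 * tree.predict(X) - 1)
    return out


def residual_partial_corr(x, y, z):
    """Partial correlation via correlating OLS residuals of x|z and y|z."""
    z1 = np.column_stack([np.ones(len(z)), z])
    rx = x - z1 @ np.linalg.lstsq(z1, x, rcond=None)[0]
    ry = y - z1 @ np.linalg.lstsq(z1, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def bfs_shortest_length(adj, source, target):
    """Hop count of the shortest path in an adjacency dict, or None."""
    if source == target:
        return 0
    seen = {source}
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v == target:
                    return d
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
    return None


def enumerate_all_shortest_paths(adj, source, target):
    """All shortest paths between two nodes by breadth-first enumeration."""
    best = bfs_shortest_length(adj, source, target)
    if best is None:
        return []
    paths = []
    stack = [[source]]
    while stack:
        path = stack.pop()
        if len(path) - 1 > best:
            continue
        last = path[-1]
        if last == target and len(path) - 1 == best:
            paths.append(path)
            continue
        for v in adj.get(last, ()):
            if v not in path:
                stack.append(path + [v])
    return paths


def hypergeom_upper_tail_exact(k, M, n, N):
    """P(X >= k) via exact integer combinatorics (Fraction-free, math.comb)."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(M, n) + 1):
        if n - j > N - M:
            continue
        acc += math.comb(M, j) * math.comb(N - M, n - j)
    return acc / total


def hypergeom_upper_tail_enumerate(k, M, n, N):
    """P(X >= k) by brute-force enumeration of all C(N, n) draws."""
    marked = set(range(M))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def bh_stepup(p):
    """Hand-rolled Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def ks_two_sample_bruteforce(x, y):
    """Sup |F1 - F2| evaluated on a dense pooled grid, the long way."""
    pooled = np.unique(np.concatenate([x, y]))
    best = 0.0
    for v in pooled:
        f1 = np.mean(np.asarray(x) <= v)
        f2 = np.mean(np.asarray(y) <= v)
        best = max(best, abs(f1 - f2))
    return best
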