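"""Independent reference implementations used only to check the package.

These deliberately share no code with ``nogoa``: the nonnegative lasso is
solved by plain projected gradient descent, ancestor sets by repeated BFS,
and true-path propagation by per-gene set unions.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def pg_nonneg_lasso(target, dictionary, lam, tol=1e-8, max_iter=200_000):
    """Projected-gradient solver for
    min_{g>=0} 1/2||target - g^T dictionary||^2 + lam * sum(g)."""
    X = np.asarray(dictionary, dtype=float).T  # |T| x (N-1)
    y = np.asarray(target, dtype=float).ravel()
    n = X.shape[1]
    lip = np.linalg.norm(X, 2) ** 2
    if lip == 0.0:
        return np.zeros(n)
    step = 1.0 / lip
    g = np.zeros(n)
    for _ in range(max_iter):
        grad = X.T @ (X @ g - y) + lam
        g_new = np.maximum(0.0, g - step * grad)
        if np.max(np.abs(g_new - g)) < tol * step:
            g = g_new
            break
        g = g_new
    return g


def pg_objective(g, target, dictionary, lam):
    resid = np.asarray(target, float).ravel() - np.asarray(g) @ np.asarray(
        dictionary, float)
    return 0.5 * float(resid @ resid) + lam * float(np.sum(g))


def bfs_ancestors(edges, term):
    """Ancestors via breadth-first search over child->parent edge pairs."""
    parents = {}
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
    seen, queue = set(), deque([term])
    while queue:
        node = queue.popleft()
        for p in parents.get(node, ()):
            if p not in seen:
                seen.add(p)
                queue.append(p)
    return seen


def propagate_by_sets(direct_pairs, edges, term_universe):
    """gene -> closed term set, by unioning ancestor sets of direct terms."""
    out = {}
    for gene, term in direct_pairs:
        closure = {term} | bfs_ancestors(edges, term)
        out.setdefault(gene, set()).update(closure & set(term_universe))
    return out
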