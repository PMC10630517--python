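"""Independent brute-force oracles used to validate the library.

Everything here is deliberately naive (loops, power iteration, exhaustive
enumeration, truncated series) and shares no code with the implementation.
"""

from __future__ import annotations

from itertools import permutations as iter_permutations

import numpy as np


def power_iteration_eig(matrix: np.ndarray, tol: float = 1e-12, max_iter: int = 100_000):
    """Full eigendecomposition of a symmetric matrix by power iteration with
    deflation, largest |eigenvalue| first. Returns (values, vectors)."""
    a = matrix.astype(float).copy()
    n = a.shape[0]
    rng = np.random.default_rng(12345)
    vals, vecs = [], []
    for _ in range(n):
        v = rng.standard_normal(n)
        v /= np.linalg.norm(v)
        lam = 0.0
        for _ in range(max_iter):
            w = a @ v
            norm = np.linalg.norm(w)
            if norm < tol:  # remaining spectrum is (numerically) zero
                lam = 0.0
                break
            w /= norm
            if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
                v = w
                lam = float(v @ a @ v)
                break
            v = w
        else:
            lam = float(v @ a @ v)
        vals.append(lam)
        vecs.append(v.copy())
        a = a - lam * np.outer(v, v)
    return np.array(vals), np.column_stack(vecs)


def loop_alignment(mode: np.ndarray, sc: np.ndarray) -> float:
    """Double-sum form of the mode alignment, by explicit loops."""
    n = len(mode)
    total = 0.0
    for n1 in range(n):
        for n2 in range(n):
            total += sc[n1, n2] * mode[n1] * mode[n2]
    return total


def loop_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook covariance / (sigma sigma) Pearson correlation by loops."""
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    sa = (sum((x - ma) ** 2 for x in a) / n) ** 0.5
    sb = (sum((y - mb) ** 2 for y in b) / n) ** 0.5
    return cov / (sa * sb)


def normal_equations(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients from the normal equations."""
    return np.linalg.solve(design.T @ design, design.T @ y)


def expm_series(matrix: np.ndarray, terms: int = 50) -> np.ndarray:
    """Truncated Taylor series for the matrix exponential."""
    out = np.eye(matrix.shape[0])
    term = np.eye(matrix.shape[0])
    for k in range(1, terms + 1):
        term = term @ matrix / k
        out = out + term
    return out


def mfpt_linear_system(adj: np.ndarray) -> np.ndarray:
    """First-passage times by solving, for each target j, the linear system
    T(i -> j) = 1 + sum_k P(i, k) T(k -> j) over i != j."""
    n = adj.shape[0]
    p = adj / adj.sum(axis=1, keepdims=True)
    out = np.zeros((n, n))
    for j in range(n):
        others = [i for i in range(n) if i != j]
        a = np.eye(n - 1) - p[np.ix_(others, others)]
        t = np.linalg.solve(a, np.ones(n - 1))
        for row, i in enumerate(others):
            out[i, j] = t[row]
    return out


def enumerate_shortest_paths(costs: np.ndarray) -> np.ndarray:
    """All-pairs shortest path costs by exhaustive enumeration of simple
    paths (viable only for n <= 7)."""
    n = costs.shape[0]
    best = np.full((n, n), np.inf)
    np.fill_diagonal(best, 0.0)
    nodes = list(range(n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            for k in range(0, n - 1):
                inner = [x for x in nodes if x not in (i, j)]
                for mid in iter_permutations(inner, k):
                    path = [i, *mid, j]
                    cost = sum(costs[a, b] for a, b in zip(path[:-1], path[1:]))
                    best[i, j] = min(best[i, j], cost)
    return best


def matching_sets(adj_bool: np.ndarray, i: int, j: int) -> float:
    """Jaccard of neighbor sets via Python set operations."""
    gi = {k for k in range(len(adj_bool)) if adj_bool[i, k]} - {i, j}
    gj = {k for k in range(len(adj_bool)) if adj_bool[j, k]} - {i, j}
    union = gi | gj
    return len(gi & gj) / len(union) if union else 0.0


def bh_stepup(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, computed directly."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return adj
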