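"""Brute-force graph oracles, independent of the implementations under test.

All-pairs shortest paths are enumerated explicitly by depth-first search
over simple paths, so degree, betweenness and closeness can be computed
straight from their definitions on tiny graphs.
"""

from itertools import permutations

import numpy as np


def all_shortest_paths(adj: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """All shortest directed paths s -> t, by exhaustive DFS."""
    n = len(adj)
    best: list[tuple[int, ...]] = []
    best_len = [n + 1]

    def dfs(path):
        u = path[-1]
        if len(path) - 1 > best_len[0]:
            return
        if u == t and len(path) > 1:
            if len(path) - 1 < best_len[0]:
                best_len[0] = len(path) - 1
                best.clear()
            if len(path) - 1 == best_len[0]:
                best.append(tuple(path))
            return
        for v in range(n):
            if adj[u, v] and v not in path:
                dfs(path + [v])

    dfs([s])
    return best


def bf_degree(adj: np.ndarray):
    n = len(adj)
    c_in = adj.sum(axis=0) / (n - 1)
    c_out = adj.sum(axis=1) / (n - 1)
    return c_in, c_out, c_in + c_out


def bf_betweenness(adj: np.ndarray, symmetric: bool) -> np.ndarray:
    n = len(adj)
    raw = np.zeros(n)
    pairs = (
        [(s, t) for s, t in permutations(range(n), 2) if s < t]
        if symmetric
        else list(permutations(range(n), 2))
    )
    for s, t in pairs:
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for i in range(n):
            if i in (s, t):
                continue
            through = sum(1 for p in paths if i in p[1:-1])
            raw[i] += through / len(paths)
    norm = 2.0 if symmetric else 1.0
    return norm * raw / ((n - 1) * (n - 2))


def bf_closeness(adj: np.ndarray) -> np.ndarray:
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        dists = []
        for j in range(n):
            if j == i:
                continue
            paths = all_shortest_paths(adj, i, j)
            if paths:
                dists.append(len(paths[0]) - 1)
        r = len(dists) + 1
        if dists:
            out[i] = ((r - 1) / (n - 1)) * ((r - 1) / sum(dists))
    return out


def dominant_eigenpair(adj: np.ndarray):
    """Spectral radius and a basis test for the left eigenproblem."""
    w = np.linalg.eigvals(adj.T)
    rho = float(np.max(np.abs(w))) if len(w) else 0.0
    return rho, w


def dominant_is_defective(adj: np.ndarray) -> bool:
    """True when power iteration cannot converge: nilpotent adjacency or a
    defective dominant eigenvalue (geometric < algebraic multiplicity)."""
    rho, w = dominant_eigenpair(adj)
    if rho < 1e-8:
        return bool(adj.any())  # nilpotent but nonzero
    alg = int(np.sum(np.abs(w - rho) < 1e-6))
    geo = adj.shape[0] - np.linalg.matrix_rank(adj.T - rho * np.eye(len(adj)), tol=1e-8)
    return geo < alg
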