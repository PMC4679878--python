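"""Independent brute-force oracles for small graphs.

Everything here is deliberately naive (exhaustive path enumeration, direct
double sums, dense eigendecomposition) and shares no code with the package's
implementations.
"""

from __future__ import annotations

import itertools

import numpy as np

REL_TOL = 1e-9


def enumerate_shortest_paths(w: np.ndarray, s: int, t: int):
    """All minimum-length simple paths s -> t with edge length 1/weight.

    Returns (min_length, list of node-tuples); empty list if unreachable.
    """
    n = w.shape[0]
    best: list[tuple] = []
    best_len = np.inf

    def dfs(node, visited, length, path):
        nonlocal best, best_len
        if length > best_len * (1 + REL_TOL):
            return
        if node == t:
            if length < best_len * (1 - REL_TOL):
                best, best_len = [tuple(path)], length
            elif abs(length - best_len) <= REL_TOL * max(best_len, 1.0):
                best.append(tuple(path))
            return
        for nxt in range(n):
            if w[node, nxt] > 0 and nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                dfs(nxt, visited, length + 1.0 / w[node, nxt], path)
                path.pop()
                visited.remove(nxt)

    dfs(s, {s}, 0.0, [s])
    return best_len, best


def distances_oracle(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for s in range(n):
        for t in range(n):
            if s != t:
                d[s, t] = enumerate_shortest_paths(w, s, t)[0]
    return d


def path_length_oracle(w: np.ndarray) -> float:
    d = distances_oracle(w)
    off = ~np.eye(w.shape[0], dtype=bool)
    vals = d[off]
    return float(vals[np.isfinite(vals)].mean())


def betweenness_oracle(w: np.ndarray) -> np.ndarray:
    """Normalized node BC over ordered endpoint pairs via path enumeration."""
    n = w.shape[0]
    bc = np.zeros(n)
    for h in range(n):
        for j in range(n):
            if h == j:
                continue
            _, paths = enumerate_shortest_paths(w, h, j)
            if not paths:
                continue
            sigma = len(paths)
            for v in range(n):
                if v in (h, j):
                    continue
                through = sum(1 for p in paths if v in p)
                bc[v] += through / sigma
    return bc / ((n - 1) * (n - 2))


def edge_betweenness_oracle(w: np.ndarray) -> dict:
    """Normalized EBC over ordered endpoint pairs via path enumeration."""
    n = w.shape[0]
    ebc = {
        (i, j): 0.0 for i in range(n) for j in range(i + 1, n) if w[i, j] > 0
    }
    for h in range(n):
        for j in range(n):
            if h == j:
                continue
            _, paths = enumerate_shortest_paths(w, h, j)
            if not paths:
                continue
            sigma = len(paths)
            for p in paths:
                for a, b in zip(p, p[1:]):
                    ebc[(min(a, b), max(a, b))] += 1.0 / sigma
    return {e: v / (n * (n - 1)) for e, v in ebc.items()}


def clustering_oracle(w: np.ndarray):
    """Per-node geometric-mean triangle clustering by direct triple loop."""
    n = w.shape[0]
    ci = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        t = 0.0
        for j in range(n):
            for h in range(n):
                t += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        t /= 2.0
        ci[i] = 2.0 * t / (k * (k - 1))
    return ci, float(ci.mean())


def modularity_oracle(w: np.ndarray, module_of, gamma: float = 1.0) -> float:
    """Direct double sum over all ordered node pairs (including u = v)."""
    n = w.shape[0]
    l = w.sum()
    strength = w.sum(axis=1)
    q = 0.0
    for u in range(n):
        for v in range(n):
            if module_of[u] == module_of[v]:
                q += w[u, v] - gamma * strength[u] * strength[v] / l
    return q / l


def components_oracle(w: np.ndarray) -> int:
    """Connected-component count via plain DFS reachability."""
    n = w.shape[0]
    seen = set()
    comps = 0
    for s in range(n):
        if s in seen:
            continue
        comps += 1
        stack = [s]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(v for v in range(n) if w[u, v] > 0 and v not in seen)
    return comps


def k4_cf_expectation(theta_percentile: float = 5.0):
    """Exact CF expectation on the unit-weight complete graph K4.

    All node BCs are 0, so the periphery is all 4 nodes; all edge drives are
    equal, so every walk takes exactly one uniformly chosen incident edge.
    Enumerates every (start set, edge choice) outcome with its probability.

    Returns (per-load expected rho, expected CF, per-load variances).
    """
    n = 4
    nbrs = {u: [v for v in range(n) if v != u] for u in range(n)}
    exp_rho, var_rho = [], []
    for t in range(1, n + 1):
        vals, probs = [], []
        for starts in itertools.combinations(range(n), t):
            p_start = 1.0 / len(list(itertools.combinations(range(n), t)))
            for choice in itertools.product(*(nbrs[s] for s in starts)):
                edges = {frozenset((s, c)) for s, c in zip(starts, choice)}
                # rank of the edge union = touched nodes - components
                nodes = set().union(*edges)
                adj = {u: set() for u in nodes}
                for e in edges:
                    a, b = tuple(e)
                    adj[a].add(b)
                    adj[b].add(a)
                seen, comps = set(), 0
                for s in nodes:
                    if s in seen:
                        continue
                    comps += 1
                    stack = [s]
                    while stack:
                        u = stack.pop()
                        if u in seen:
                            continue
                        seen.add(u)
                        stack.extend(adj[u] - seen)
                rank = len(nodes) - comps
                vals.append(t / rank if rank >= 1 else 0.0)
                probs.append(p_start / 3**t)
        vals, probs = np.array(vals), np.array(probs)
        mean = float((vals * probs).sum())
        exp_rho.append(mean)
        var_rho.append(float((probs * (vals - mean) ** 2).sum()))
    return np.array(exp_rho), float(np.sum(exp_rho)), np.array(var_rho)
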