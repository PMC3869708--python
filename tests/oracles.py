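"""Independent brute-force oracles used to verify the fast implementations.

Everything here is deliberately naive: exhaustive enumeration over paths,
triples, subsets, scans and pairs. These never share code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_density(values: np.ndarray, directed: bool) -> float:
    v = np.nan_to_num(np.asarray(values, dtype=float))
    n = v.shape[0]
    edges = 0
    pairs = 0
    for i in range(n):
        for j in range(n):
            if i == j or (not directed and j < i):
                continue
            pairs += 1
            present = v[i, j] != 0 or (not directed and v[j, i] != 0)
            edges += bool(present)
    return edges / pairs


def brute_transitivity(values: np.ndarray, rule: str) -> float:
    w = np.nan_to_num(np.asarray(values, dtype=float))
    n = w.shape[0]
    total = closed = 0
    for a, b, c in itertools.permutations(range(n), 3):
        if w[a, b] > 0 and w[b, c] > 0:
            total += 1
            if rule == "any":
                ok = w[a, c] > 0
            elif rule == "min":
                ok = w[a, c] >= min(w[a, b], w[b, c])
            else:
                ok = w[a, c] > max(w[a, b], w[b, c])
            closed += bool(ok)
    return float("nan") if total == 0 else 100.0 * closed / total


def brute_betweenness(values: np.ndarray, directed: bool) -> np.ndarray:
    """Betweenness by exhaustive enumeration of all shortest paths.

    BFS gives pairwise distances; a depth-bounded DFS then enumerates every
    shortest simple path and tallies interior-node incidences.
    """
    v = np.nan_to_num(np.asarray(values, dtype=float))
    if not directed:
        v = np.maximum(v, v.T)
    a = v > 0
    n = a.shape[0]
    adj = [list(np.nonzero(a[i])[0]) for i in range(n)]

    def bfs_dist(s: int) -> np.ndarray:
        dist = np.full(n, np.inf)
        dist[s] = 0
        q = [s]
        while q:
            u = q.pop(0)
            for w in adj[u]:
                if dist[w] == np.inf:
                    dist[w] = dist[u] + 1
                    q.append(w)
        return dist

    bc = np.zeros(n)
    for s in range(n):
        dist = bfs_dist(s)
        for t in range(n):
            if t == s or not np.isfinite(dist[t]):
                continue
            bound = int(dist[t])
            paths: list[tuple[int, ...]] = []

            def dfs(node: int, path: tuple[int, ...]) -> None:
                if node == t:
                    paths.append(path)
                    return
                if len(path) - 1 >= bound:
                    return
                for w in adj[node]:
                    if w not in path:
                        dfs(w, path + (w,))

            dfs(s, (s,))
            sigma = len(paths)
            through = np.zeros(n)
            for p in paths:
                for v_ in p[1:-1]:
                    through[v_] += 1
            bc += through / sigma
    if not directed:
        bc /= 2.0
    return bc


def brute_cliques(values: np.ndarray, min_size: int = 3) -> set[frozenset[int]]:
    """All maximal cliques of size >= min_size by power-set enumeration."""
    v = np.nan_to_num(np.asarray(values, dtype=float))
    a = np.maximum(v, v.T) > 0
    np.fill_diagonal(a, False)
    n = a.shape[0]
    nodes = range(n)

    def is_clique(sub: tuple[int, ...]) -> bool:
        return all(a[i, j] for i, j in itertools.combinations(sub, 2))

    cliques = [frozenset(sub) for k in range(1, n + 1)
               for sub in itertools.combinations(nodes, k) if is_clique(sub)]
    maximal = {c for c in cliques if not any(c < d for d in cliques)}
    return {c for c in maximal if len(c) >= min_size}


def brute_sri_matrix(scans, ids) -> np.ndarray:
    """Per-dyad simple-ratio tallies by direct iteration over scans."""
    n = len(ids)
    out = np.zeros((n, n))
    for ai, a in enumerate(ids):
        for bi, b in enumerate(ids):
            if ai == bi:
                continue
            x = y_a = y_b = 0
            for scan in scans:
                a_in, b_in = a in scan.present, b in scan.present
                a_out, b_out = a in scan.absent, b in scan.absent
                if a_in and b_in:
                    x += 1
                elif a_in and b_out:
                    y_a += 1
                elif b_in and a_out:
                    y_b += 1
            denom = x + y_a + y_b
            out[ai, bi] = np.nan if denom == 0 else x / denom
    return out


def brute_interaction_tally(events, behavior, ids) -> np.ndarray:
    n = len(ids)
    idx = {a: k for k, a in enumerate(ids)}
    out = np.zeros((n, n))
    wanted = ("play", "greeting", "social_licking") if behavior == "all_social" else (behavior,)
    for e in events:
        if e.behavior in wanted:
            out[idx[e.initiator], idx[e.recipient]] += 1
    return out


def brute_kendall_tau_b(x, y) -> float:
    """Kendall tau-b by exhaustive pair concordance counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = tie_x = tie_y = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tie_x += 1
            tie_y += 1
        elif dx == 0:
            tie_x += 1
        elif dy == 0:
            tie_y += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tie_x) * (n0 - tie_y))
    return (conc - disc) / denom
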