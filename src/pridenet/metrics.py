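"""Group- and node-level network metrics for small social networks.

All metrics operate on labelled square matrices (weights >= 0, NaN marking
missing dyads, zero diagonal). The group-level metrics are density, strong
transitivity, and maximal cliques; the node-level metrics are weighted
degree (in/out for directed networks), and betweenness centrality computed
with Brandes' shortest-path accumulation. A density-matched Erdős–Rényi
null generator supports the permutation comparisons.

Betweenness and clique enumeration default to the *binarized* graph
(edge iff weight > 0): the path-count definition of betweenness,
``B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st``, is about counts of shortest paths, and
on a valued matrix the weighted variant (1/weight edge lengths, so stronger
ties are shorter) is available behind a flag.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .matrices import LabeledMatrix, binarize, symmetrize

TRANSITIVITY_RULES = ("min", "max", "any")


def _clean(values: np.ndarray) -> np.ndarray:
    v = np.array(values, dtype=float)
    v[np.isnan(v)] = 0.0
    np.fill_diagonal(v, 0.0)
    return v


# ---------------------------------------------------------------------------
# group-level metrics
# ---------------------------------------------------------------------------

def density(values: np.ndarray, directed: bool) -> float:
    """Fraction of realized ties out of all possible ties.

    1 marks a complete graph, 0 an empty one. Missing dyads count as absent
    ties.
    """
    v = _clean(values)
    n = v.shape[0]
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    edges = np.count_nonzero(v)
    possible = n * (n - 1)
    if not directed:
        edges = np.count_nonzero(np.triu(np.maximum(v, v.T), 1))
        possible //= 2
    return edges / possible


def strong_transitivity(values: np.ndarray, rule: str = "min") -> float:
    """Percentage of open directed two-paths closed by a strong enough tie.

    Over all ordered triples (A, B, C) of distinct nodes with w(A,B) > 0 and
    w(B,C) > 0, the closing tie A→C satisfies:

    * ``any`` — w(A,C) > 0;
    * ``min`` — w(A,C) >= min(w(A,B), w(B,C)) (at least as strong as the
      weaker supporting tie);
    * ``max`` — w(A,C) > max(w(A,B), w(B,C)) (stronger than both).

    Directionality is respected throughout. Returns a percentage in
    [0, 100]; NaN when no supported triple exists.
    """
    if rule not in TRANSITIVITY_RULES:
        raise ValueError(f"unknown transitivity rule {rule!r}; expected one of {TRANSITIVITY_RULES}")
    w = _clean(values)
    n = w.shape[0]
    if n < 3:
        raise ValueError("transitivity undefined for fewer than 3 nodes")

    # vectorized over (A, B, C): support[a, b, c] = w(a,b)>0 and w(b,c)>0
    ab = w[:, :, None]          # w(a, b)
    bc = w.T[None, :, :]        # w(b, c) -> indexed [a?, b, c]; broadcast below
    bc = np.broadcast_to(w[None, :, :], (n, n, n))   # w(b, c) at [a, b, c]
    ab = np.broadcast_to(w[:, :, None], (n, n, n))   # w(a, b) at [a, b, c]
    ac = np.broadcast_to(w[:, None, :], (n, n, n))   # w(a, c) at [a, b, c]
    distinct = (
        ~np.eye(n, dtype=bool)[:, :, None]
        & ~np.eye(n, dtype=bool)[None, :, :]
        & ~np.eye(n, dtype=bool)[:, None, :]
    )
    support = (ab > 0) & (bc > 0) & distinct
    total = int(support.sum())
    if total == 0:
        return float("nan")
    if rule == "any":
        closed = ac > 0
    elif rule == "min":
        closed = ac >= np.minimum(ab, bc)
    else:
        closed = ac > np.maximum(ab, bc)
    return 100.0 * int((support & closed).sum()) / total


# ---------------------------------------------------------------------------
# node-level metrics
# ---------------------------------------------------------------------------

def node_degrees(values: np.ndarray, ids: Sequence[str], directed: bool) -> pd.DataFrame:
    """Weighted degree table, raw and normalized.

    Directed: outdegree(i) = row sum (bouts initiated), indegree(i) =
    column sum (bouts received). Undirected: degree = row sum of the
    symmetric matrix. Normalized values are
    ``100 * raw / ((n - 1) * max off-diagonal weight)`` — the percentage of
    the ceiling attained if the individual carried the network's strongest
    observed tie to every other member — and 0 on an all-zero matrix.
    """
    v = _clean(values)
    n = v.shape[0]
    if n < 2:
        raise ValueError("degrees undefined for fewer than 2 nodes")
    top = v.max()
    scale = 100.0 / ((n - 1) * top) if top > 0 else 0.0
    if directed:
        out = v.sum(axis=1)
        inn = v.sum(axis=0)
        df = pd.DataFrame(
            {
                "outdegree": out,
                "indegree": inn,
                "outdegree_norm": out * scale,
                "indegree_norm": inn * scale,
            },
            index=list(ids),
        )
    else:
        sym = np.maximum(v, v.T)
        deg = sym.sum(axis=1)
        df = pd.DataFrame({"degree": deg, "degree_norm": deg * scale}, index=list(ids))
    df.index.name = "id"
    return df


def _brandes(adj: list[list[int]], n: int, lengths: np.ndarray | None = None) -> np.ndarray:
    """Brandes betweenness accumulation over BFS/Dijkstra shortest-path DAGs."""
    bc = np.zeros(n)
    for s in range(n):
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, np.inf)
        dist[s] = 0.0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        if lengths is None:
            queue = [s]
            head = 0
            while head < len(queue):
                v = queue[head]
                head += 1
                order.append(v)
                for w in adj[v]:
                    if dist[w] == np.inf:
                        dist[w] = dist[v] + 1
                        queue.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
        else:
            seen = np.zeros(n, dtype=bool)
            heap: list[tuple[float, int]] = [(0.0, s)]
            while heap:
                d, v = heapq.heappop(heap)
                if seen[v]:
                    continue
                seen[v] = True
                order.append(v)
                for w in adj[v]:
                    nd = d + lengths[v, w]
                    if nd < dist[w] - 1e-12:
                        dist[w] = nd
                        sigma[w] = sigma[v]
                        preds[w] = [v]
                        heapq.heappush(heap, (nd, w))
                    elif abs(nd - dist[w]) <= 1e-12 and not seen[w]:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc


def betweenness(
    values: np.ndarray,
    ids: Sequence[str],
    directed: bool = True,
    weighted: bool = False,
) -> pd.DataFrame:
    """Betweenness centrality ``B(v) = Σ_{s≠v≠t} σ_st(v) / σ_st``.

    σ_st is the number of shortest s→t paths and σ_st(v) the number passing
    through v; disconnected pairs contribute nothing. By default paths are
    counted on the binarized graph; with ``weighted=True`` edge lengths are
    reciprocal weights (strong ties are short). Normalization is
    ``100 * B / ((n-1)(n-2))`` for directed and ``100 * 2B / ((n-1)(n-2))``
    for undirected networks.
    """
    v = _clean(values)
    n = v.shape[0]
    if n < 3:
        raise ValueError("betweenness undefined for fewer than 3 nodes")
    if not directed:
        v = np.maximum(v, v.T)
    adj = [list(np.nonzero(v[i])[0]) for i in range(n)]
    lengths = None
    if weighted:
        with np.errstate(divide="ignore"):
            lengths = np.where(v > 0, 1.0 / np.where(v > 0, v, 1.0), np.inf)
    bc = _brandes(adj, n, lengths)
    if not directed:
        bc = bc / 2.0
        norm = 100.0 * 2.0 * bc / ((n - 1) * (n - 2))
    else:
        norm = 100.0 * bc / ((n - 1) * (n - 2))
    df = pd.DataFrame({"betweenness": bc, "betweenness_norm": norm}, index=list(ids))
    df.index.name = "id"
    return df


# ---------------------------------------------------------------------------
# cliques
# ---------------------------------------------------------------------------

def _bron_kerbosch(
    r: set[int], p: set[int], x: set[int], neigh: list[set[int]], out: list[frozenset[int]]
) -> None:
    if not p and not x:
        out.append(frozenset(r))
        return
    pivot = max(p | x, key=lambda u: len(p & neigh[u]))
    for v in sorted(p - neigh[pivot]):
        _bron_kerbosch(r | {v}, p & neigh[v], x & neigh[v], neigh, out)
        p = p - {v}
        x = x | {v}


def find_cliques(
    values: np.ndarray,
    ids: Sequence[str],
    min_size: int = 3,
    symmetrization: str = "union",
) -> list[tuple[str, ...]]:
    """Maximal cliques of size >= ``min_size``, in lexicographic order.

    The matrix is binarized and, if directed, symmetrized first: ``union``
    places an undirected tie when either direction is present,
    ``intersection`` only when both are. Enumeration is Bron–Kerbosch with
    pivoting; each returned clique is a sorted id tuple, maximal (no clique
    is a subset of another).
    """
    v = _clean(values)
    if symmetrization == "union":
        a = np.maximum(v, v.T) > 0
    elif symmetrization == "intersection":
        a = (v > 0) & (v.T > 0)
    else:
        raise ValueError(f"unknown symmetrization {symmetrization!r}")
    n = v.shape[0]
    np.fill_diagonal(a, False)
    neigh = [set(np.nonzero(a[i])[0]) for i in range(n)]
    raw: list[frozenset[int]] = []
    _bron_kerbosch(set(), set(range(n)), set(), neigh, raw)
    ids = list(ids)
    cliques = [tuple(sorted(ids[i] for i in c)) for c in raw if len(c) >= min_size]
    return sorted(cliques)


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

def random_network(
    n: int,
    density: float,
    directed: bool,
    seed: int | np.random.Generator | None = None,
    ids: Sequence[str] | None = None,
) -> LabeledMatrix:
    """Density-matched binary random (Erdős–Rényi G(n, m)-style) network.

    Places exactly ``round(density * possible_edges)`` edges uniformly at
    random, so each draw realizes the requested density exactly (up to edge
    granularity). Reproducible under a seed.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must lie in [0, 1], got {density}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if directed:
        slots = [(i, j) for i in range(n) for j in range(n) if i != j]
    else:
        slots = [(i, j) for i in range(n) for j in range(i + 1, n)]
    m = int(round(density * len(slots)))
    vals = np.zeros((n, n))
    if m:
        chosen = rng.choice(len(slots), size=m, replace=False)
        for k in chosen:
            i, j = slots[k]
            vals[i, j] = 1.0
            if not directed:
                vals[j, i] = 1.0
    ids = tuple(ids) if ids is not None else tuple(f"N{k:02d}" for k in range(n))
    return LabeledMatrix(ids=ids, values=vals, name="random")


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class NetworkReport:
    """Group- and node-level metrics for one network."""

    network_name: str
    density: float
    strong_transitivity: float
    node_metrics: pd.DataFrame
    cliques: list[tuple[str, ...]]
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "network_name": self.network_name,
            "density": self.density,
            "strong_transitivity": self.strong_transitivity,
            "node_metrics": self.node_metrics.reset_index().to_dict(orient="records"),
            "cliques": [list(c) for c in self.cliques],
            "meta": self.meta,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))


def network_report(
    matrix: LabeledMatrix,
    directed: bool,
    name: str | None = None,
    transitivity_rule: str = "min",
    weighted_betweenness: bool = False,
    clique_min_size: int = 3,
    clique_symmetrization: str = "union",
) -> NetworkReport:
    """Compute the full metric suite for one network matrix."""
    v = matrix.values
    ids = matrix.ids
    n = len(ids)
    deg = node_degrees(v, ids, directed)
    node = deg
    if n >= 3:
        btw = betweenness(v, ids, directed=directed, weighted=weighted_betweenness)
        node = deg.join(btw)
        trans = strong_transitivity(v, rule=transitivity_rule)
        cliques = find_cliques(v, ids, min_size=clique_min_size, symmetrization=clique_symmetrization)
    else:
        trans = float("nan")
        cliques = []
    return NetworkReport(
        network_name=name or matrix.name or "network",
        density=density(v, directed),
        strong_transitivity=trans,
        node_metrics=node,
        cliques=cliques,
        meta={
            "directed": directed,
            "transitivity_rule": transitivity_rule,
            "weighted_betweenness": weighted_betweenness,
            "clique_min_size": clique_min_size,
            "clique_symmetrization": clique_symmetrization,
            "degree_normalization": "100 * raw / ((n-1) * max off-diagonal weight)",
            "betweenness_normalization": (
                "100 * B / ((n-1)(n-2))" if directed else "100 * 2B / ((n-1)(n-2))"
            ),
            "n": n,
        },
    )
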