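"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive and self-contained so it cannot share
a bug with the implementation under test: Floyd-Warshall distances, direct
triangle counting, a Kuratowski-subdivision planarity search, a greedy PMFG
built on that search, the 2x2-contingency phi formula, and a hand-rolled
pooled t-test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- distances

def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, math.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def brute_aspl(adj: np.ndarray) -> float:
    dist = floyd_warshall(adj)
    n = adj.shape[0]
    vals = [dist[i, j] for i in range(n) for j in range(i + 1, n)]
    if any(math.isinf(v) for v in vals):
        raise ValueError("disconnected")
    return sum(vals) / len(vals)


def brute_diameter(adj: np.ndarray) -> int:
    dist = floyd_warshall(adj)
    n = adj.shape[0]
    vals = [dist[i, j] for i in range(n) for j in range(i + 1, n)]
    if any(math.isinf(v) for v in vals):
        raise ValueError("disconnected")
    return int(max(vals))


def brute_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        neigh = [j for j in range(n) if adj[i, j]]
        k = len(neigh)
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(neigh, 2) if adj[a, b]
        )
        total += links / (k * (k - 1) / 2)
    return total / n


# ---------------------------------------------------------------- planarity

def _neighbors(edges: set[frozenset], v) -> set:
    return {next(iter(e - {v})) for e in edges if v in e}


def _has_disjoint_paths(edges, pairs, branch, used):
    """Backtracking search for internally vertex-disjoint paths.

    ``pairs`` is the list of (u, v) endpoints still to connect; interior
    vertices must avoid ``branch`` vertices and any vertex in ``used``.
    """
    if not pairs:
        return True
    (u, v), rest = pairs[0], pairs[1:]

    # enumerate simple u-v paths whose interiors avoid branch/used vertices
    stack = [(u, [u])]
    while stack:
        node, path = stack.pop()
        for nxt in _neighbors(edges, node):
            if nxt == v:
                interior = set(path[1:])
                if _has_disjoint_paths(edges, rest, branch, used | interior):
                    return True
            elif nxt not in path and nxt not in branch and nxt not in used:
                stack.append((nxt, path + [nxt]))
    return False


def _has_subdivision_k5(nodes, edges, degree):
    cand = [v for v in nodes if degree[v] >= 4]
    for branch in itertools.combinations(cand, 5):
        pairs = list(itertools.combinations(branch, 2))
        if _has_disjoint_paths(edges, pairs, set(branch), set()):
            return True
    return False


def _has_subdivision_k33(nodes, edges, degree):
    cand = [v for v in nodes if degree[v] >= 3]
    for side_a in itertools.combinations(cand, 3):
        remaining = [v for v in cand if v not in side_a]
        for side_b in itertools.combinations(remaining, 3):
            if side_a > side_b:  # each unordered pair of sides once
                continue
            pairs = [(a, b) for a in side_a for b in side_b]
            branch = set(side_a) | set(side_b)
            if _has_disjoint_paths(edges, pairs, branch, set()):
                return True
    return False


def brute_is_planar(adj: np.ndarray) -> bool:
    """Planarity by exhaustive Kuratowski-subdivision search (small graphs).

    A graph is non-planar iff it contains a subdivision of K5 or K3,3.
    Quick accepts: at most 8 edges is always planar (the smallest
    non-planar subdivisions need 9 or 10 edges); quick reject: more than
    3n - 6 edges on n >= 3 nodes violates Euler's bound.
    """
    n = adj.shape[0]
    edges = {
        frozenset((i, j))
        for i in range(n)
        for j in range(i + 1, n)
        if adj[i, j]
    }
    if len(edges) <= 8:
        return True
    if n >= 3 and len(edges) > 3 * n - 6:
        return False
    nodes = list(range(n))
    degree = {v: len(_neighbors(edges, v)) for v in nodes}
    if _has_subdivision_k5(nodes, edges, degree):
        return False
    if _has_subdivision_k33(nodes, edges, degree):
        return False
    return True


def brute_pmfg_edges(weights: np.ndarray, labels: list[str]) -> set[tuple[str, str]]:
    """Greedy PMFG by exhaustive planarity checking at every step.

    Candidates sorted by weight descending, ties broken lexicographically
    by (smaller word, larger word); an edge is kept iff the graph stays
    planar per :func:`brute_is_planar`.  No early exit, no shortcuts.
    """
    n = weights.shape[0]
    order = sorted(labels)
    pos = {w: labels.index(w) for w in labels}
    candidates = sorted(
        ((a, b) for i, a in enumerate(order) for b in order[i + 1:]),
        key=lambda e: (-weights[pos[e[0]], pos[e[1]]], e[0], e[1]),
    )
    adj = np.zeros((n, n), dtype=np.int8)
    idx = {w: k for k, w in enumerate(order)}
    kept: set[tuple[str, str]] = set()
    for a, b in candidates:
        i, j = idx[a], idx[b]
        adj[i, j] = adj[j, i] = 1
        if brute_is_planar(adj):
            kept.add((a, b))
        else:
            adj[i, j] = adj[j, i] = 0
    return kept


# --------------------------------------------------------------- statistics

def phi_from_table(x: np.ndarray, y: np.ndarray) -> float:
    """Phi coefficient from the 2x2 contingency table of two binary vectors."""
    n11 = int(((x == 1) & (y == 1)).sum())
    n10 = int(((x == 1) & (y == 0)).sum())
    n01 = int(((x == 0) & (y == 1)).sum())
    n00 = int(((x == 0) & (y == 0)).sum())
    denom = math.sqrt(
        (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    )
    if denom == 0:
        raise ValueError("degenerate margin")
    return (n11 * n00 - n10 * n01) / denom


def pooled_t(x, y) -> tuple[float, int]:
    """Textbook pooled two-sample t statistic and degrees of freedom."""
    x, y = list(map(float, x)), list(map(float, y))
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    ssx = sum((v - mx) ** 2 for v in x)
    ssy = sum((v - my) ** 2 for v in y)
    df = nx + ny - 2
    sp2 = (ssx + ssy) / df
    t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return t, df
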