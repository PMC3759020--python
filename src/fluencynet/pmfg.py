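"""Planar Maximally Filtered Graph (PMFG) construction.

The complete correlation network on N words is filtered to a maximal planar
subgraph by a single greedy pass: candidate edges are visited in descending
weight order and inserted whenever the graph stays planar.  The result is
connected, planar, and has exactly 3(N-2) edges, so its mean degree
6(N-2)/N is fixed by N alone.  Edges are then binarised to uniform weight 1.

Determinism: correlations estimated from a few dozen binary profiles
produce many exact ties, so candidate edges with equal weight are ordered
lexicographically by their (smaller, larger) word pair.  Identical input
matrices therefore always yield identical networks.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from networkx.algorithms.planarity import LRPlanarity

from .correlation import CorrelationMatrix

logger = logging.getLogger(__name__)

__all__ = ["SemanticNetwork", "PMFGSizeError", "build_pmfg", "is_planar_with"]


class PMFGSizeError(ValueError):
    """Raised for inputs with fewer than 3 nodes (3(N-2) is degenerate)."""


@dataclass
class SemanticNetwork:
    """Unweighted, undirected, connected planar word network (PMFG output).

    ``provenance`` records how the network was built (network kind such as
    SMCN or WMCN, group label, and a digest of the source correlations).
    """

    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    @property
    def vocabulary(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def to_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for key, value in self.provenance.items():
            g.graph[str(key)] = str(value)
        for node in g.nodes:
            g.nodes[node]["word"] = str(node)
        nx.write_graphml(g, path)

    def to_edgelist_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["word_a", "word_b"])
            for a, b in sorted(self.edge_set()):
                writer.writerow([a, b])


def _is_planar(graph: nx.Graph) -> bool:
    """Left-right planarity test, skipping embedding construction.

    Runs the orientation and testing phases of networkx's LR implementation
    only; building the planar embedding roughly doubles the cost and is not
    needed for a yes/no answer inside the greedy pass.
    """
    if graph.number_of_nodes() > 2 and graph.number_of_edges() > 3 * graph.number_of_nodes() - 6:
        return False
    lr = LRPlanarity(graph)
    for v in lr.G:
        lr.adjs[v] = list(lr.G[v])
    for v in lr.G:
        if lr.height[v] is None:
            lr.height[v] = 0
            lr.roots.append(v)
            lr.dfs_orientation(v)
    for v in lr.DG:
        lr.ordered_adjs[v] = sorted(lr.DG[v], key=lambda x: lr.nesting_depth[(v, x)])
    return all(lr.dfs_testing(v) for v in lr.roots)


def is_planar_with(g: SemanticNetwork | nx.Graph, e: tuple) -> bool:
    """True iff the graph plus candidate edge ``e`` admits a planar embedding.

    ``e`` must not already be present.  Graphs with at most 8 edges are
    always planar (the smallest non-planar graphs, subdivisions of K5 and
    K3,3, need 10 and 9 edges), so the test short-circuits there.
    """
    graph = g.graph if isinstance(g, SemanticNetwork) else g
    u, v = e
    if graph.has_edge(u, v):
        raise ValueError(f"edge {e!r} already present")
    trial = graph.copy()
    trial.add_edge(u, v)
    if trial.number_of_edges() <= 8:
        return True
    return _is_planar(trial)


def build_pmfg(
    c: CorrelationMatrix,
    network_kind: str | None = None,
    group_label: str | None = None,
) -> SemanticNetwork:
    """Greedy single-pass PMFG of a correlation (similarity) matrix.

    All N(N-1)/2 candidate edges are sorted by correlation, descending
    (signed value, not magnitude), with ties broken lexicographically by
    word pair; each is added iff the graph stays planar.  The pass stops as
    soon as 3(N-2) edges are placed — a planar simple graph cannot hold
    more, so the early exit is equivalent to scanning every candidate.

    Two shortcuts avoid planarity tests that cannot fail: an edge joining
    two different connected components preserves planarity (the components
    embed independently), and any graph with at most 8 edges is planar.
    """
    n = c.n_words
    if n < 3:
        raise PMFGSizeError(f"PMFG needs at least 3 words, got {n}")
    if not np.isfinite(c.values).all():
        raise ValueError("correlation matrix contains non-finite entries")

    # lexicographic vocabulary order makes the tie-break label-driven,
    # independent of the column order of the input matrix
    order_vocab = sorted(c.vocabulary)
    cm = c.restrict(order_vocab)
    weights = cm.values
    iu, ju = np.triu_indices(n, 1)
    rank = np.lexsort((ju, iu, -weights[iu, ju]))

    target = 3 * (n - 2)
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(order_vocab)

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_edges = 0
    for k in rank:
        if n_edges == target:
            break
        i, j = int(iu[k]), int(ju[k])
        u, v = order_vocab[i], order_vocab[j]
        ri, rj = find(i), find(j)
        if ri != rj:
            graph.add_edge(u, v)
            parent[ri] = rj
            n_edges += 1
            continue
        graph.add_edge(u, v)
        if n_edges + 1 <= 8 or _is_planar(graph):
            n_edges += 1
        else:
            graph.remove_edge(u, v)

    nx.set_edge_attributes(graph, 1, "weight")  # binarised
    provenance = {
        "network_kind": network_kind or "",
        "group_label": group_label or "",
        "n_words": n,
        "source_digest": _digest(cm.values),
    }
    return SemanticNetwork(graph=graph, provenance=provenance)


def _digest(values: np.ndarray) -> str:
    import hashlib

    return hashlib.sha256(np.ascontiguousarray(values).tobytes()).hexdigest()[:16]
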