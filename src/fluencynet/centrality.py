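"""Word impact scores by leave-one-word-out network re-estimation.

The impact score of word i is the change in average shortest path length
when the word is removed from the sample and the network is re-estimated:

    WC(i) = ASPL(network rebuilt without i) - ASPL(full network)

A positive score means removing the word lengthens average paths, i.e. the
word shortens paths (supports the spread of activation) while present; a
negative score means the word inhibits it.  The canonical semantics rebuild
the PMFG from the correlation submatrix with the word's row and column
deleted; a faster induced-subgraph mode (delete the node from the full
network without re-filtering) is available but is NOT the canonical
definition and is labelled accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix
from .netmetrics import aspl
from .nullmodels import TTestResult, two_sample_t
from .pmfg import build_pmfg

logger = logging.getLogger(__name__)

__all__ = ["ImpactResult", "impact_scores", "compare_impact", "impact_table"]


@dataclass(frozen=True)
class ImpactResult:
    """Impact score of one word in one group's network."""

    word: str
    wc: float
    group_label: str = ""


def _aspl_largest_component(graph: nx.Graph) -> float:
    if nx.is_connected(graph):
        return aspl(graph)
    component = max(nx.connected_components(graph), key=len)
    return aspl(graph.subgraph(component))


def impact_scores(
    c: CorrelationMatrix,
    group_label: str = "",
    mode: str = "rebuild",
) -> list[ImpactResult]:
    """Impact score for every word of a correlation matrix.

    ``mode="rebuild"`` (canonical): for each word, delete its row and column
    from the correlation matrix, rebuild the PMFG from scratch, and take the
    ASPL difference from the full network.  ``mode="subgraph"`` instead
    removes the node from the full PMFG without re-filtering (ASPL on the
    largest remaining component if removal disconnects it); this is a fast
    approximation, not the canonical definition.

    Needs a vocabulary of at least 4 words so every leave-one-out network
    has the 3 nodes a PMFG requires.
    """
    if c.n_words < 4:
        raise ValueError(
            f"impact scores need at least 4 words, got {c.n_words}"
        )
    if mode not in ("rebuild", "subgraph"):
        raise ValueError(f"unknown mode {mode!r}")
    vocab = sorted(c.vocabulary)
    full = build_pmfg(c, group_label=group_label)
    full_aspl = aspl(full)
    results = []
    for word in vocab:
        if mode == "rebuild":
            rest = [w for w in vocab if w != word]
            net = build_pmfg(c.restrict(rest), group_label=group_label)
            loo_aspl = aspl(net)
        else:
            g = full.graph.copy()
            g.remove_node(word)
            loo_aspl = _aspl_largest_component(g)
        results.append(
            ImpactResult(word=word, wc=loo_aspl - full_aspl, group_label=group_label)
        )
    return results


def compare_impact(
    a: list[ImpactResult], b: list[ImpactResult]
) -> TTestResult:
    """Pooled two-sample t-test over the two groups' impact vectors.

    Both lists must cover the same vocabulary in the same order (word-matched
    networks); df = 2 * vocabulary - 2.
    """
    if [r.word for r in a] != [r.word for r in b]:
        raise ValueError("impact lists must cover the same words in the same order")
    return two_sample_t([r.wc for r in a], [r.wc for r in b])


def impact_table(results: list[ImpactResult]) -> pd.DataFrame:
    """Impact scores as a table sorted by absolute impact, descending."""
    frame = pd.DataFrame(
        {
            "word": [r.word for r in results],
            "group": [r.group_label for r in results],
            "wc": [r.wc for r in results],
        }
    )
    return frame.reindex(
        frame["wc"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
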