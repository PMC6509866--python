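"""Globally independent genes from the directed causal network.

A gene is globally independent when it has in-degree 0 in the directed
network — a source of a feed-forward subnetwork or an isolated node — or
when it belongs to a feedback subnetwork, formalised as a nontrivial
strongly connected component (or a self-loop).  Independent genes are the
candidate dominant regulators passed to stepwise predictor selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .core_io import CausalNetwork

__all__ = ["ScreenResult", "find_feedback_components", "screen_independent"]


def _digraph(net: CausalNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edge_pairs())
    return g


def find_feedback_components(net: CausalNetwork) -> list[frozenset[str]]:
    """Feedback subnetworks: SCCs of size >= 2 plus self-loop singletons."""
    g = _digraph(net)
    out = []
    for comp in nx.strongly_connected_components(g):
        if len(comp) >= 2 or g.has_edge(next(iter(comp)), next(iter(comp))):
            out.append(frozenset(comp))
    return sorted(out, key=lambda c: sorted(c))


@dataclass(frozen=True)
class ScreenResult:
    """Independent genes with their topological category."""

    independent_genes: frozenset[str]
    category: dict[str, str]  # gene -> source | isolated | feedback
    scc_partition: tuple[frozenset[str], ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "category": self.category[g]}
            for g in sorted(self.independent_genes)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "category"])


def screen_independent(
    net: CausalNetwork, *, include_isolated: bool = True
) -> ScreenResult:
    """Select in-degree-0 nodes and feedback-component members.

    Categories: ``feedback`` (member of a nontrivial SCC or self-loop,
    taking precedence), ``isolated`` (no directed edge at all), ``source``
    (in-degree 0 with outgoing edges).  ``include_isolated=False`` drops
    nodes whose every pair failed the cascade from the candidate pool.
    """
    g = _digraph(net)
    feedback = set().union(*find_feedback_components(net)) if net.directed_edges else set()
    category: dict[str, str] = {}
    for v in net.nodes:
        if v in feedback:
            category[v] = "feedback"
        elif g.in_degree(v) == 0:
            category[v] = "isolated" if g.out_degree(v) == 0 else "source"
    if not include_isolated:
        category = {v: c for v, c in category.items() if c != "isolated"}
    scc = tuple(
        sorted((frozenset(c) for c in nx.strongly_connected_components(g)), key=sorted)
    )
    return ScreenResult(
        independent_genes=frozenset(category),
        category=category,
        scc_partition=scc,
    )
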