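"""Multi-interaction diff-gene network and degree-based feature-gene selection.

The network is the induced subgraph of the typed interaction edge list on
the diff-gene set, kept as a multigraph: a gene pair linked through two
interaction channels contributes two edges, and a node's degree counts
that multiplicity.  Feature genes are the nodes whose degree strictly
exceeds a cut (or, alternatively, the top-k by degree with ties kept).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .core_io import TypedEdgeList, UNDIRECTED_TYPES

__all__ = ["MultiNetwork", "build_network", "select_by_degree", "select_top_k", "induced_subnetwork"]


@dataclass(frozen=True)
class MultiNetwork:
    """Undirected typed multigraph on a fixed node set."""

    nodes: frozenset[str]
    edges: TypedEdgeList
    n_dropped_external: int = 0  # input edges touching genes outside `nodes`

    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for a, b, t in self.edges:
            g.add_edge(a, b, key=t, interaction_type=t)
        return g

    def degree(self) -> dict[str, int]:
        """Per-node degree counting edge multiplicity across types."""
        deg = {v: 0 for v in self.nodes}
        for a, b, _ in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def unique_neighbor_degree(self) -> dict[str, int]:
        """Alternative degree ignoring type multiplicity (unique partners)."""
        nbrs: dict[str, set[str]] = {v: set() for v in self.nodes}
        for a, b, _ in self.edges:
            nbrs[a].add(b)
            nbrs[b].add(a)
        return {v: len(s) for v, s in nbrs.items()}

    def degree_frame(self) -> pd.DataFrame:
        deg = self.degree()
        return pd.DataFrame(
            {"gene_id": sorted(deg), "degree": [deg[g] for g in sorted(deg)]}
        )

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_network(diff_genes: set[str], edges: TypedEdgeList) -> MultiNetwork:
    """Induced typed subgraph of ``edges`` on ``diff_genes``.

    Only the three undirected gene-gene channels are admitted; edges with
    an endpoint outside ``diff_genes`` are dropped and counted.
    """
    kept = []
    dropped = 0
    for a, b, t in edges:
        if t not in UNDIRECTED_TYPES:
            continue
        if a in diff_genes and b in diff_genes:
            kept.append((a, b, t))
        else:
            dropped += 1
    return MultiNetwork(
        nodes=frozenset(diff_genes),
        edges=TypedEdgeList.build(kept),
        n_dropped_external=dropped,
    )


def select_by_degree(net: MultiNetwork, degree_cut: int, *, multiplicity: bool = True) -> set[str]:
    """Nodes whose degree is strictly greater than ``degree_cut``.

    ``multiplicity=False`` counts unique interaction partners instead of
    typed-edge multiplicity.
    """
    deg = net.degree() if multiplicity else net.unique_neighbor_degree()
    return {v for v, d in deg.items() if d > degree_cut}


def select_top_k(net: MultiNetwork, k: int, *, multiplicity: bool = True) -> set[str]:
    """Top-``k`` nodes by degree; nodes tied with the k-th degree are kept."""
    if k < 1:
        raise ValueError("k must be >= 1")
    deg = net.degree() if multiplicity else net.unique_neighbor_degree()
    if not deg:
        return set()
    ranked = sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))
    if k >= len(ranked):
        return set(deg)
    threshold = ranked[k - 1][1]
    return {v for v, d in deg.items() if d >= threshold}


def induced_subnetwork(net: MultiNetwork, genes: set[str]) -> MultiNetwork:
    """Subgraph on ``genes`` (which must be existing nodes); degrees recomputed."""
    unknown = set(genes) - set(net.nodes)
    if unknown:
        raise KeyError(f"unknown genes: {sorted(unknown)}")
    kept = [(a, b, t) for a, b, t in net.edges if a in genes and b in genes]
    return MultiNetwork(nodes=frozenset(genes), edges=TypedEdgeList.build(kept))
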