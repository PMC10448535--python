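"""Score-filtered protein–protein interaction graphs and degree-rule core selection.

The interaction network keeps only high-confidence edges (combined score
strictly above the cutoff, default 0.9 on the 0–1 scale) as an undirected
simple graph.  Core targets are the genes whose unweighted degree strictly
exceeds a multiple (default 2) of the mean degree, with the mean taken after
isolated nodes are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .errors import PipelineUsageError


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected simple graph of genes; edges carry a ``score`` in [0, 1]."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def degree(self, node: str) -> int:
        return int(self.graph.degree(node))

    def degree_table(self) -> list[tuple[str, int]]:
        """(gene, degree) sorted by degree descending, then name."""
        return sorted(
            ((n, int(d)) for n, d in self.graph.degree()), key=lambda nd: (-nd[1], nd[0])
        )

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def build_network(
    pairs: Iterable[tuple[str, str, float]],
    min_score: float = 0.9,
    restrict_to: Iterable[str] | None = None,
) -> InteractionNetwork:
    """Build the simple graph of edges with score strictly > ``min_score``.

    Scores must already be on the 0–1 scale.  Reciprocal duplicate rows
    collapse to one undirected edge (keeping the maximum score); self-loops
    are ignored.  With ``restrict_to``, both endpoints must belong to it.
    """
    allowed = set(restrict_to) if restrict_to is not None else None
    g = nx.Graph()
    if allowed is not None:
        g.add_nodes_from(allowed)
    for a, b, score in pairs:
        if a == b or score <= min_score:
            continue
        if allowed is not None and (a not in allowed or b not in allowed):
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], score)
        else:
            g.add_edge(a, b, score=score)
    return InteractionNetwork(g)


def drop_isolated(network: InteractionNetwork) -> InteractionNetwork:
    """Remove degree-0 nodes; edges are unchanged."""
    g = network.graph.copy()
    g.remove_nodes_from([n for n, d in g.degree() if d == 0])
    return InteractionNetwork(g)


def select_core(network: InteractionNetwork, multiplier: float = 2.0) -> list[str]:
    """Genes with degree strictly > ``multiplier`` × mean degree.

    The mean is computed over the nodes remaining after isolated-node removal
    (the convention of analyzing the displayed, connected network).  Returned
    sorted by degree descending, then name.  An edgeless network is a usage
    error.
    """
    connected = drop_isolated(network)
    if connected.graph.number_of_edges() == 0:
        raise PipelineUsageError("select_core needs a network with at least one edge")
    degrees = dict(connected.graph.degree())
    mean_degree = sum(degrees.values()) / len(degrees)
    threshold = multiplier * mean_degree
    core = [n for n, d in degrees.items() if d > threshold]
    return sorted(core, key=lambda n: (-degrees[n], n))


def subnetwork(network: InteractionNetwork, genes: Iterable[str]) -> InteractionNetwork:
    """Induced subgraph on ``genes`` (e.g. the core set, for re-computed degrees)."""
    return InteractionNetwork(network.graph.subgraph(set(genes)).copy())
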