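"""Protein-interaction network container.

A thin, validated wrapper around :class:`networkx.Graph` holding an
undirected protein-protein interaction network (PPIN) with per-edge
confidence scores in [0, 1].  Node identifiers are opaque, case-sensitive
strings; edges are unordered pairs stored canonically as sorted tuples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = ["InteractionNetwork", "canonical_edge"]


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Return the unordered pair (u, v) in canonical sorted order."""
    return (u, v) if u <= v else (v, u)


@dataclass
class InteractionNetwork:
    """Undirected PPIN with confidence-scored edges.

    Invariants enforced on construction: no self-loops, unordered pairs are
    unique, every edge endpoint is a node, every score lies in [0, 1].
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            s = data.get("score")
            if s is None or not (0.0 <= s <= 1.0):
                raise ValueError(f"edge ({u!r}, {v!r}) has invalid score {s!r}")

    @classmethod
    def from_scored_edges(
        cls,
        edges: Mapping[tuple[str, str], float],
        extra_nodes: Iterable[str] = (),
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(extra_nodes)
        for (u, v), score in edges.items():
            g.add_edge(u, v, score=float(score))
        return cls(g)

    # -- basic views -------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {canonical_edge(u, v) for u, v in self.graph.edges}

    def score(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["score"]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self) -> dict[str, set[str]]:
        """Neighbour sets keyed by node; the sampler's working structure."""
        return {n: set(self.graph.neighbors(n)) for n in self.graph.nodes}

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.graph.nodes)
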