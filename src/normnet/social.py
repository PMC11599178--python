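"""Directed friend-nomination graph and social-network centralities.

Nodes are people; a directed edge A→B means A nominated B as a
particularly close friend.  Four per-person metrics are produced:
in-degree (received nominations), out-degree (sent nominations),
betweenness centrality on the directed graph, and the self-reported
real-life network size.

Betweenness of node v sums, over ordered pairs (s, t) with s ≠ t ≠ v,
the fraction of shortest s→t paths that pass through v; disconnected
pairs contribute nothing.  Values are raw (unnormalized) by default —
the class-network scale this models reports small raw-like values — and
a ``normalized`` flag plus an undirected (symmetrized) option are
provided since survey studies vary on both.  Computation uses the
Brandes accumulation algorithm via networkx.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError


@dataclass
class SocialGraph:
    """Directed nomination graph plus per-node real-life network size."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    real_life_size: dict[str, int] = field(default_factory=dict)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def out_degree(self, node: str) -> int:
        return sum(1 for a, _ in self.edges if a == node)

    def in_degree(self, node: str) -> int:
        return sum(1 for _, b in self.edges if b == node)


def build_graph(edges: Sequence[tuple[str, str]],
                sizes: Mapping[str, int] | None = None,
                nodes: Iterable[str] | None = None) -> SocialGraph:
    """Validate an edge list into a :class:`SocialGraph`.

    Self-nominations raise :class:`ValidationError`; duplicate edges are
    collapsed with a warning.  If *nodes* is given, edges must reference
    declared nodes only.
    """
    declared = set(nodes) if nodes is not None else None
    seen: dict[tuple[str, str], int] = {}
    for a, b in edges:
        if a == b:
            raise ValidationError(f"self-nomination {a}->{b}")
        if declared is not None and (a not in declared or b not in declared):
            raise ValidationError(f"edge {a}->{b} references undeclared node")
        seen[(a, b)] = seen.get((a, b), 0) + 1
    dups = [e for e, k in seen.items() if k > 1]
    if dups:
        warnings.warn(f"collapsed {len(dups)} duplicate edge(s): {dups[:5]}")
    unique_edges = tuple(seen)
    node_set = declared if declared is not None else \
        {n for e in unique_edges for n in e}
    if sizes:
        node_set = set(node_set) | set(sizes)
        for n, v in sizes.items():
            if v < 0:
                raise ValidationError(f"negative real-life size for {n}")
    return SocialGraph(
        nodes=tuple(sorted(node_set)),
        edges=unique_edges,
        real_life_size=dict(sizes) if sizes else {},
    )


def degree_centrality(g: SocialGraph) -> pd.DataFrame:
    """Per-node in-/out-degree counts (exact edge counts)."""
    nxg = g.to_networkx()
    return pd.DataFrame(
        {
            "in_degree": [nxg.in_degree(n) for n in g.nodes],
            "out_degree": [nxg.out_degree(n) for n in g.nodes],
        },
        index=pd.Index(g.nodes, name="node"),
    )


def betweenness(g: SocialGraph, directed: bool = True,
                normalized: bool = False) -> pd.Series:
    """Betweenness centrality per node (Brandes accumulation).

    Directed and raw (unnormalized) by default; ``directed=False``
    symmetrizes the nomination graph first.
    """
    nxg = g.to_networkx()
    if not directed:
        nxg = nxg.to_undirected()
    bc = nx.betweenness_centrality(nxg, normalized=normalized)
    return pd.Series([bc[n] for n in g.nodes],
                     index=pd.Index(g.nodes, name="node"), name="betweenness")


def centrality_table(g: SocialGraph, directed: bool = True,
                     normalized: bool = False) -> pd.DataFrame:
    """The four social-network metrics per node.

    Columns: ``in_degree``, ``out_degree``, ``betweenness``,
    ``real_life_size`` (NaN where no size was reported).
    """
    tab = degree_centrality(g)
    tab["betweenness"] = betweenness(g, directed=directed,
                                     normalized=normalized)
    tab["real_life_size"] = [g.real_life_size.get(n) for n in g.nodes]
    return tab
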