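"""Treatment-combination network.

Nodes are treatments, sized by the number of distinct users mentioning the
treatment; edges join treatments co-mentioned within the sentence window,
weighted by the number of distinct users who co-mentioned them (users, not
raw instances).  Built on :mod:`networkx` so the graph can be exported to
GraphML for any network visualiser.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .corpus import Catalog, FeatureKind, FeatureMention

__all__ = ["NetworkEdge", "build_network", "network_edges", "treatment_user_counts"]


@dataclass(frozen=True)
class NetworkEdge:
    """One unordered treatment pair and its distinct-user weight."""

    treatment_a: str
    treatment_b: str
    n_users: int

    def __post_init__(self) -> None:
        if self.treatment_a >= self.treatment_b:
            raise ValueError("edge endpoints must be canonically ordered (a < b)")
        if self.n_users < 1:
            raise ValueError("an edge requires at least one user")


def treatment_user_counts(
    mentions: Iterable[FeatureMention], catalog: Catalog
) -> dict[str, int]:
    """Distinct users mentioning each treatment (node-size attribute)."""
    users: dict[str, set[str]] = {}
    for m in mentions:
        if catalog.kind_of(m.feature_id) is FeatureKind.TREATMENT:
            users.setdefault(m.feature_id, set()).add(m.user_id)
    return {t: len(u) for t, u in users.items()}


def build_network(
    combination_records: Iterable[tuple[str, str, str]],
    node_user_counts: Mapping[str, int],
) -> nx.Graph:
    """Assemble the combination graph from ``(user_id, a, b)`` records.

    Each unordered treatment pair becomes one edge with ``n_users`` = number
    of distinct users co-mentioning it; nodes carry ``n_users`` = distinct
    users mentioning the treatment at all.  Nodes with no mentions are
    omitted; isolated nodes (mentioned but never combined) are kept.
    """
    edge_users: dict[tuple[str, str], set[str]] = {}
    for user_id, a, b in combination_records:
        x, y = (a, b) if a < b else (b, a)
        edge_users.setdefault((x, y), set()).add(user_id)
    g = nx.Graph()
    for t in sorted(node_user_counts):
        g.add_node(t, n_users=int(node_user_counts[t]))
    for (a, b) in sorted(edge_users):
        for t in (a, b):
            if t not in g:
                g.add_node(t, n_users=0)
        g.add_edge(a, b, n_users=len(edge_users[(a, b)]))
    return g


def network_edges(graph: nx.Graph) -> list[NetworkEdge]:
    """Canonical, sorted edge list of a combination graph."""
    out = []
    for a, b, data in graph.edges(data=True):
        x, y = (a, b) if a < b else (b, a)
        out.append(NetworkEdge(x, y, int(data["n_users"])))
    return sorted(out, key=lambda e: (e.treatment_a, e.treatment_b))
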