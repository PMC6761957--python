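"""Exact graph statistics on the multiplex trait network.

All quantities are exact counts (no heuristics): complexes are the type I
connected components (which are necessarily cliques, since identity of
supports is transitive); stability degrees are type II in/out degrees;
dissociability statistics (density, triangles, diameter) live on the type
III layer; pivotality is measured by type D triplets, the colored motif
{s, t, u} with t–s and t–u overlapping (type III) and s–u disjoint (type IV).

Density of the type III layer is 2k / (N(N−1)) with k its edge count and N
the total trait count; the triangle proportion divides the triangle count by
the number of *possible* triplets N(N−1)(N−2)/6 — deliberately not the
transitivity/clustering-coefficient denominator, which only counts connected
triads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx

from .network import MultiplexTraitNetwork

__all__ = [
    "DegreeRecord",
    "TripletRecord",
    "Type3Stats",
    "MetricsReport",
    "find_complexes",
    "type2_degrees",
    "type3_stats",
    "count_d_triplets",
    "summarize",
]


@dataclass(frozen=True)
class DegreeRecord:
    """Type II in/out degree of one node, with its stability flag.

    A node with in-degree 0 and positive out-degree is "precarious"
    (unstable): every related trait is more widely distributed than it.
    Positive in-degree marks a node as relatively stable.
    """

    node_id: int
    in_degree: int
    out_degree: int

    @property
    def flag(self) -> str:
        if self.in_degree > 0:
            return "stable"
        if self.out_degree > 0:
            return "precarious"
        return "isolated"


@dataclass(frozen=True)
class TripletRecord:
    node_id: int
    d_centrality: int


@dataclass(frozen=True)
class Type3Stats:
    k: int
    density: float
    n_triangles: int
    proportion_triangles: float
    diameter: int


@dataclass
class MetricsReport:
    """All scalar network metrics plus per-node degree/centrality tables."""

    n_nodes: int
    n_complexes: int
    complex_members: list[list[int]]
    n_edges: dict[str, int]
    type3: Type3Stats
    n_typeD: int
    degrees: list[DegreeRecord]
    triplets: list[TripletRecord]

    def to_dict(self) -> dict:
        d = {
            "schema_version": 1,
            "n_nodes": self.n_nodes,
            "n_complexes": self.n_complexes,
            "complex_members": self.complex_members,
            "n_edges_I": self.n_edges["I"],
            "n_edges_II": self.n_edges["II"],
            "n_edges_III": self.n_edges["III"],
            "n_edges_IV": self.n_edges["IV"],
            "density_III": self.type3.density,
            "n_triangles_III": self.type3.n_triangles,
            "proportion_triangles_III": self.type3.proportion_triangles,
            "diameter_III": self.type3.diameter,
            "n_typeD": self.n_typeD,
        }
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def find_complexes(net: MultiplexTraitNetwork) -> list[set[int]]:
    """Connected components of the type I layer with ≥ 2 nodes.

    Each component is verified to be a clique (support identity is an
    equivalence relation, so anything else indicates a broken network).
    Returned sorted by (size, lowest node_id).
    """
    if net.edge_counts()["I"] == 0:
        return []
    g = net.graph("I")
    out: list[set[int]] = []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        n = len(comp)
        if sub.number_of_edges() != n * (n - 1) // 2:
            raise AssertionError(f"type I component {sorted(comp)} is not a clique")
        out.append(set(comp))
    out.sort(key=lambda c: (len(c), min(c)))
    return out


def type2_degrees(net: MultiplexTraitNetwork) -> list[DegreeRecord]:
    """Per-node counts of incoming and outgoing type II (nesting) edges."""
    in_deg = net.adj_II.sum(axis=0)
    out_deg = net.adj_II.sum(axis=1)
    return [
        DegreeRecord(i + 1, int(in_deg[i]), int(out_deg[i]))
        for i in range(net.n_nodes)
    ]


def type3_stats(net: MultiplexTraitNetwork) -> Type3Stats:
    """Edge count, density, triangles, triangle proportion and diameter of layer III.

    N is the total trait count of the network (isolated nodes included); the
    diameter of a disconnected layer is the largest finite eccentricity over
    its connected components, single-node components contributing 0.
    """
    n = net.n_nodes
    if n < 2:
        raise ValueError("density undefined for N < 2")
    if n < 3:
        raise ValueError("triangle proportion undefined for N < 3")
    k = net.edge_counts()["III"]
    density = 2.0 * k / (n * (n - 1))
    n_triangles = net.triangle_count_III
    proportion = n_triangles / (n * (n - 1) * (n - 2) / 6.0)
    g = net.graph("III")
    diameter = 0
    for comp in nx.connected_components(g):
        if len(comp) > 1:
            diameter = max(diameter, nx.diameter(g.subgraph(comp)))
    return Type3Stats(k, density, n_triangles, proportion, diameter)


def count_d_triplets(net: MultiplexTraitNetwork) -> tuple[int, list[TripletRecord]]:
    """Count type D triplets and each node's centrality in them.

    A type D triplet is an unordered triple {s, t, u} with t–s and t–u of
    type III and s–u of type IV; t is the central (pivotal-candidate) node.
    The per-node centrality counts unordered {s, u} pairs, so the total over
    nodes equals the triplet count.
    """
    per_node = net.d_centrality
    records = [TripletRecord(i + 1, int(per_node[i])) for i in range(net.n_nodes)]
    return int(per_node.sum()), records


def summarize(net: MultiplexTraitNetwork) -> MetricsReport:
    """Aggregate every reported statistic into one serializable report."""
    complexes = find_complexes(net)
    degrees = type2_degrees(net)
    t3 = type3_stats(net)
    n_typeD, triplets = count_d_triplets(net)
    return MetricsReport(
        n_nodes=net.n_nodes,
        n_complexes=len(complexes),
        complex_members=[sorted(c) for c in complexes],
        n_edges=net.edge_counts(),
        type3=t3,
        n_typeD=n_typeD,
        degrees=degrees,
        triplets=triplets,
    )
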