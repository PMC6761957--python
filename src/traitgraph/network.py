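"""Multiplex trait networks: typed co-occurrence relations between trait pairs.

Every pair of traits from *different* characters falls into exactly one of
four relations, decided purely by set algebra on their taxon supports:

* **type I** — identical supports (the traits always co-occur; such ties
  chain into "complexes");
* **type II** — strictly nested supports, stored as a directed edge from the
  nested trait to the inclusive one;
* **type III** — overlapping but non-nested supports (the traits co-occur in
  some taxa and evolve apart in others);
* **type IV** — disjoint supports (the traits are never found together).

Pairs of traits belonging to the same character are never connected.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import cached_property
from typing import AbstractSet

import networkx as nx
import numpy as np

from .matrix import TraitMatrix

__all__ = [
    "Relation",
    "classify_pair",
    "MultiplexTraitNetwork",
    "build_network",
    "edge_table",
]


class Relation(Enum):
    """Outcome of comparing two trait supports A and B.

    ``edge_type`` is the layer symbol ("I".."IV"); ``direction`` is "AB"
    (A nested in B), "BA", or None for the undirected relations.
    """

    IDENTICAL = ("I", None)
    NESTED_AB = ("II", "AB")
    NESTED_BA = ("II", "BA")
    OVERLAPPING = ("III", None)
    DISJOINT = ("IV", None)

    def __init__(self, edge_type: str, direction: str | None) -> None:
        self.edge_type = edge_type
        self.direction = direction


def classify_pair(support_a: AbstractSet[str], support_b: AbstractSet[str]) -> Relation:
    """Classify one cross-character pair of taxon supports.

    Returns :data:`Relation.IDENTICAL` (type I), ``NESTED_AB``/``NESTED_BA``
    (type II, directed from the nested to the inclusive trait),
    ``OVERLAPPING`` (type III) or ``DISJOINT`` (type IV).  Both supports must
    be non-empty — recoding guarantees this for real traits.
    """
    a, b = frozenset(support_a), frozenset(support_b)
    if not a or not b:
        raise ValueError("trait supports must be non-empty")
    if a == b:
        return Relation.IDENTICAL
    if a < b:
        return Relation.NESTED_AB
    if b < a:
        return Relation.NESTED_BA
    if a.isdisjoint(b):
        return Relation.DISJOINT
    return Relation.OVERLAPPING


@dataclass
class MultiplexTraitNetwork:
    """One node per trait; four typed edge layers over the same node set.

    Edges are stored internally as boolean adjacency matrices (node order =
    node_id order); the public ``edges_*`` views materialize sorted tuples of
    1-based node_ids, with undirected pairs keyed ``(low, high)`` and type II
    pairs ordered nested → inclusive.
    """

    tm: TraitMatrix
    adj_I: np.ndarray
    adj_II: np.ndarray  # adj_II[i, j] True iff support(i) ⊊ support(j)
    adj_III: np.ndarray
    adj_IV: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.tm.N

    @staticmethod
    def _undirected_pairs(adj: np.ndarray) -> frozenset[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(adj, k=1))
        return frozenset(zip((ii + 1).tolist(), (jj + 1).tolist()))

    @cached_property
    def edges_I(self) -> frozenset[tuple[int, int]]:
        return self._undirected_pairs(self.adj_I)

    @cached_property
    def edges_II(self) -> frozenset[tuple[int, int]]:
        ii, jj = np.nonzero(self.adj_II)
        return frozenset(zip((ii + 1).tolist(), (jj + 1).tolist()))

    @cached_property
    def edges_III(self) -> frozenset[tuple[int, int]]:
        return self._undirected_pairs(self.adj_III)

    @cached_property
    def edges_IV(self) -> frozenset[tuple[int, int]]:
        return self._undirected_pairs(self.adj_IV)

    @cached_property
    def triangle_count_III(self) -> int:
        """Unordered node triples fully connected by type III edges."""
        a = self.adj_III.astype(np.float64)  # float keeps the matmul in BLAS;
        return int(round(np.trace(a @ a @ a) / 6))  # exact below 2**53

    @cached_property
    def d_centrality(self) -> np.ndarray:
        """Per-node type D triplet centrality (unordered {s, u} pairs).

        centrality(t) = ½ Σ_{s,u} A_III[t,s] · A_IV[s,u] · A_III[u,t].
        """
        a3 = self.adj_III.astype(np.float64)
        a4 = self.adj_IV.astype(np.float64)
        per = ((a3 @ a4) * a3).sum(axis=1) / 2.0  # a3 is symmetric
        return np.rint(per).astype(np.int64)

    @cached_property
    def _edge_counts(self) -> dict[str, int]:
        return {
            "I": int(np.triu(self.adj_I, 1).sum()),
            "II": int(self.adj_II.sum()),
            "III": int(np.triu(self.adj_III, 1).sum()),
            "IV": int(np.triu(self.adj_IV, 1).sum()),
        }

    def edge_counts(self) -> dict[str, int]:
        return dict(self._edge_counts)

    def n_cross_pairs(self) -> int:
        """Number of comparable (cross-character) unordered pairs."""
        n = self.n_nodes
        chars = self.tm.character_of()
        _, counts = np.unique(chars, return_counts=True)
        return n * (n - 1) // 2 - int((counts * (counts - 1) // 2).sum())

    def graph(self, edge_type: str) -> "nx.Graph | nx.DiGraph":
        """networkx view of one layer ('I', 'II', 'III' or 'IV'); all N nodes."""
        if edge_type == "II":
            g: nx.Graph | nx.DiGraph = nx.DiGraph()
        else:
            g = nx.Graph()
        g.add_nodes_from(range(1, self.n_nodes + 1))
        g.add_edges_from(sorted(getattr(self, f"edges_{edge_type}")))
        return g

    def to_multiplex_graph(self) -> nx.MultiDiGraph:
        """All layers in one networkx MultiDiGraph with 'type'/'directed' attrs."""
        g = nx.MultiDiGraph()
        for tr in self.tm.traits:
            g.add_node(
                tr.node_id,
                label=tr.label,
                character_id=tr.character_id,
                state_symbol=tr.state_symbol,
                support_size=len(tr.support),
            )
        for etype in ("I", "III", "IV"):
            for u, v in sorted(getattr(self, f"edges_{etype}")):
                g.add_edge(u, v, type=etype, directed=False)
        for u, v in sorted(self.edges_II):
            g.add_edge(u, v, type="II", directed=True)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_multiplex_graph(), path)


def build_network(tm: TraitMatrix) -> MultiplexTraitNetwork:
    """Assemble the multiplex network by classifying every cross-character pair.

    The construction is deterministic: a given trait matrix yields exactly
    one network.  All :math:`\\binom{N}{2}` pairs are examined; same-character
    pairs receive no edge of any type.
    """
    S = tm.incidence()  # N × T bool
    sizes = S.sum(axis=1)
    inter = (S.astype(np.int64) @ S.T.astype(np.int64))
    subset = inter == sizes[:, None]  # subset[i, j]: support(i) ⊆ support(j)
    chars = tm.character_of()
    cross = chars[:, None] != chars[None, :]

    eq = subset & subset.T
    adj_I = eq & cross
    adj_II = subset & ~subset.T & cross
    adj_IV = (inter == 0) & cross
    adj_III = cross & ~eq & ~subset & ~subset.T & (inter > 0)
    for a in (adj_I, adj_II, adj_III, adj_IV):
        np.fill_diagonal(a, False)
    return MultiplexTraitNetwork(tm, adj_I, adj_II, adj_III, adj_IV)


def edge_table(net: MultiplexTraitNetwork, edge_type: str) -> str:
    """TSV listing of one edge layer (direction column for type II)."""
    lines = []
    if edge_type == "II":
        lines.append("nested_node\tinclusive_node")
        for u, v in sorted(net.edges_II):
            lines.append(f"{u}\t{v}")
    else:
        lines.append("node_a\tnode_b")
        for u, v in sorted(getattr(net, f"edges_{edge_type}")):
            lines.append(f"{u}\t{v}")
    return "\n".join(lines) + "\n"
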