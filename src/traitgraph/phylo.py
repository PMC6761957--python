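"""Reference-tree utilities: newick parsing, patristic distances, monophyly.

The trait network itself is tree-free; these helpers compare its patterns
against a user-supplied reference phylogeny — classifying nested (type II)
trait pairs by whether each endpoint's support is a clade, and providing the
distance matrix that drives the phylogenetically restricted permutation
null.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache

import dendropy
import numpy as np

from .network import MultiplexTraitNetwork

__all__ = [
    "TreeModel",
    "parse_newick",
    "is_monophyletic",
    "classify_nested_pairs",
    "NESTED_PAIR_CLASSES",
]

#: The four monophyly classes of a nested (type II) trait pair, keyed by
#: (inner support monophyletic?, outer support monophyletic?).
NESTED_PAIR_CLASSES = {
    (True, True): "clade_in_clade",
    (True, False): "clade_in_paraphyletic",
    (False, True): "paraphyletic_in_clade",
    (False, False): "paraphyletic_in_paraphyletic",
}


@dataclass
class TreeModel:
    """A rooted reference phylogeny with named leaves and branch lengths.

    "Paraphyletic" below means simply *not monophyletic with respect to the
    sampled taxa*; monophyly is assessed on the rooted tree as given.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        dupes = [t for t, c in Counter(labels).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
        self.leaves: frozenset[str] = frozenset(labels)
        missing = [
            e for e in self.tree.preorder_edge_iter()
            if e.head_node.parent_node is not None and e.length is None
        ]
        if missing:
            warnings.warn(
                "tree has edges without branch lengths; using unit lengths"
            )
            for e in missing:
                e.length = 1.0
        self._clades: set[frozenset[str]] | None = None

    def check_taxa(self, taxa) -> None:
        absent = sorted(set(taxa) - self.leaves)
        if absent:
            raise ValueError(f"taxa missing from tree: {absent}")

    def patristic_matrix(self, taxa: tuple[str, ...]) -> np.ndarray:
        """Leaf-to-leaf path-length distances, ordered like ``taxa``."""
        self.check_taxa(taxa)
        pdm = self.tree.phylogenetic_distance_matrix()
        tx = {t.label: t for t in self.tree.taxon_namespace}
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(tx[taxa[i]], tx[taxa[j]])
        return d

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets subtended by every node of the rooted tree."""
        if self._clades is None:
            out: set[frozenset[str]] = set()
            for node in self.tree.postorder_node_iter():
                out.add(
                    frozenset(
                        lf.taxon.label for lf in node.leaf_iter()
                    )
                )
            self._clades = out
        return self._clades


def parse_newick(text: str) -> TreeModel:
    """Parse a newick tree; absent branch lengths become unit lengths."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise ValueError(f"newick parse failed: {exc}") from exc
    return TreeModel(tree)


def is_monophyletic(taxon_set, tree: TreeModel) -> bool:
    """True iff some node of the rooted tree subtends exactly ``taxon_set``.

    Singletons are monophyletic by convention, as is the full leaf set.
    """
    ts = frozenset(taxon_set)
    if not ts:
        raise ValueError("empty taxon set")
    tree.check_taxa(ts)
    if len(ts) == 1:
        return True
    return ts in tree.clades()


def classify_nested_pairs(
    net: MultiplexTraitNetwork, tree: TreeModel
) -> tuple[dict[str, int], list[tuple[int, int, bool, bool, str]]]:
    """Classify every type II edge by the monophyly of its two supports.

    Returns (counts per class, per-edge rows ``(inner_node, outer_node,
    inner_mono, outer_mono, class)``).  Counts always sum to |edges_II|.
    """
    tree.check_taxa(net.tm.taxa)
    supports = {tr.node_id: tr.support for tr in net.tm.traits}
    mono_cache: dict[frozenset[str], bool] = {}

    def mono(s: frozenset[str]) -> bool:
        if s not in mono_cache:
            mono_cache[s] = is_monophyletic(s, tree)
        return mono_cache[s]

    counts = {name: 0 for name in NESTED_PAIR_CLASSES.values()}
    rows = []
    for inner, outer in sorted(net.edges_II):
        mi, mo = mono(supports[inner]), mono(supports[outer])
        cls = NESTED_PAIR_CLASSES[(mi, mo)]
        counts[cls] += 1
        rows.append((inner, outer, mi, mo, cls))
    return counts, rows
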