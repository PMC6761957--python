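"""Synthetic character matrices and fixtures.

Two generators cover the two data-generating regimes the permutation nulls
contrast: :func:`random_matrix` draws iid uniform states per cell (exactly
the equiprobable null's world), while :func:`simulate_mk_on_tree` evolves
each character independently along a phylogeny under a symmetric q-state
Markov (Mk) process, producing the phylogenetic autocorrelation that the
restricted null is designed to respect.

:func:`pivotal_motif_fixture` is a tiny hand-built trait matrix of four traits over
five taxa whose network contains four overlapping (type III) edges, two
disjoint (type IV) edges, one type III triangle and one node central in two
type D triplets — a fully worked example used throughout the tests and
docs.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import expm

from .matrix import MISSING, Character, CharacterMatrix, Trait, TraitMatrix
from .phylo import TreeModel

__all__ = ["SimulationConfig", "random_matrix", "simulate_mk_on_tree", "pivotal_motif_fixture"]


@dataclass
class SimulationConfig:
    """Knobs for synthetic matrix generation.

    ``n_states`` may be a single int (every character) or a sequence per
    character; ``rate`` is the total leaving rate of the Mk process per unit
    branch length.
    """

    n_taxa: int = 21
    n_characters: int = 120
    n_states: "int | list[int]" = 3
    missing_rate: float = 0.0
    rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_characters < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")

    def states_of(self, j: int) -> int:
        q = self.n_states if isinstance(self.n_states, int) else self.n_states[j]
        if q < 2:
            raise ValueError("characters need at least 2 states")
        return q


def _taxon_names(n: int) -> tuple[str, ...]:
    return tuple(f"t{i + 1}" for i in range(n))


def _assemble(
    cfg: SimulationConfig, states: np.ndarray, rng: np.random.Generator
) -> CharacterMatrix:
    """Integer state array (taxa × characters) → CharacterMatrix with missing."""
    cells = states.astype(str).astype(object)
    if cfg.missing_rate > 0:
        mask = rng.random(cells.shape) < cfg.missing_rate
        cells[mask] = MISSING
    characters = []
    for j in range(cfg.n_characters):
        q = cfg.states_of(j)
        characters.append(
            Character(j + 1, f"char{j + 1}", {str(s): str(s) for s in range(q)})
        )
    return CharacterMatrix(_taxon_names(cfg.n_taxa), tuple(characters), cells)


def random_matrix(cfg: SimulationConfig) -> CharacterMatrix:
    """iid uniform states per cell; MISSING inserted at ``missing_rate``."""
    rng = np.random.default_rng(cfg.seed)
    states = np.empty((cfg.n_taxa, cfg.n_characters), dtype=np.int64)
    for j in range(cfg.n_characters):
        states[:, j] = rng.integers(0, cfg.states_of(j), size=cfg.n_taxa)
    return _assemble(cfg, states, rng)


def _mk_transition(q: int, rate: float, t: float) -> np.ndarray:
    """Transition matrix of the symmetric q-state Mk process over time t.

    The rate matrix has total leaving rate ``rate`` split equally over the
    q − 1 alternative states; the exact matrix exponential is used.
    """
    Q = np.full((q, q), rate / (q - 1))
    np.fill_diagonal(Q, -rate)
    return expm(Q * t)


def simulate_mk_on_tree(cfg: SimulationConfig, tree: TreeModel) -> CharacterMatrix:
    """Evolve each character independently along ``tree`` under the Mk model.

    Root states are uniform; each branch applies the exact exponential of
    the symmetric rate matrix.  Leaf order follows the tree's taxa, so the
    matrix rows are the tree leaves.
    """
    rng = np.random.default_rng(cfg.seed)
    leaves = sorted(tree.leaves)
    if len(leaves) != cfg.n_taxa:
        raise ValueError(
            f"tree has {len(leaves)} leaves but config requests {cfg.n_taxa} taxa"
        )
    leaf_index = {name: i for i, name in enumerate(leaves)}
    states = np.empty((cfg.n_taxa, cfg.n_characters), dtype=np.int64)
    pmatrices: dict[tuple[int, float], np.ndarray] = {}

    for j in range(cfg.n_characters):
        q = cfg.states_of(j)
        node_state: dict[dendropy.Node, int] = {}
        for node in tree.tree.preorder_node_iter():
            if node.parent_node is None:
                node_state[node] = int(rng.integers(0, q))
                continue
            t = float(node.edge.length or 0.0)
            key = (q, t)
            if key not in pmatrices:
                pmatrices[key] = _mk_transition(q, cfg.rate, t)
            row = pmatrices[key][node_state[node.parent_node]]
            node_state[node] = int(rng.choice(q, p=row / row.sum()))
            if node.is_leaf():
                states[leaf_index[node.taxon.label], j] = node_state[node]
    cm = _assemble(
        SimulationConfig(
            n_taxa=cfg.n_taxa,
            n_characters=cfg.n_characters,
            n_states=cfg.n_states,
            missing_rate=cfg.missing_rate,
            rate=cfg.rate,
            seed=cfg.seed,
        ),
        states,
        rng,
    )
    return CharacterMatrix(tuple(leaves), cm.characters, cm.cells)


def pivotal_motif_fixture() -> tuple[TraitMatrix, dict[str, int]]:
    """Four traits over taxa {a..e} with a known III/IV edge pattern.

    Supports: trait "43" = {a,b}, "38" = {b,c,d}, "2" = {c,e}, "12" = {d,e},
    each from a distinct character.  Returns ``(trait_matrix, id_map)``
    where ``id_map`` maps the display labels ("2", "12", "38", "43") to
    1-based node_ids.  The network has edges_III = {38–43, 38–2, 38–12,
    2–12}, edges_IV = {43–2, 43–12}, no type I/II edges, one type III
    triangle {38, 2, 12}, diameter 2, and node "38" central in exactly two
    type D triplets.
    """
    taxa = ("a", "b", "c", "d", "e")
    supports = {
        "2": frozenset({"c", "e"}),
        "12": frozenset({"d", "e"}),
        "38": frozenset({"b", "c", "d"}),
        "43": frozenset({"a", "b"}),
    }
    traits = []
    id_map = {}
    for i, (label, sup) in enumerate(sorted(supports.items(), key=lambda x: int(x[0]))):
        traits.append(
            Trait(
                node_id=i + 1,
                character_id=i + 1,
                state_symbol="1",
                label=label,
                support=sup,
            )
        )
        id_map[label] = i + 1
    return TraitMatrix(taxa, tuple(traits)), id_map
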