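"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own vectorized code
paths: pair relations are decided by direct set predicates, triangles and
type D triplets by exhaustive enumeration over all triples, and monophyly
via dendropy's MRCA machinery.
"""

from itertools import combinations

import numpy as np
import pytest

from traitgraph import (
    CharacterMatrix,
    SimulationConfig,
    Trait,
    TraitMatrix,
    build_network,
    pivotal_motif_fixture,
    random_matrix,
)


@pytest.fixture
def motif_example():
    """(trait_matrix, id_map, network) for the four-trait worked example."""
    tm, ids = pivotal_motif_fixture()
    return tm, ids, build_network(tm)


def make_trait_matrix(supports, taxa, characters=None):
    """Hand-build a TraitMatrix from a list of support iterables.

    ``characters`` assigns a character_id per trait (default: all distinct).
    """
    if characters is None:
        characters = list(range(1, len(supports) + 1))
    traits = tuple(
        Trait(
            node_id=i + 1,
            character_id=characters[i],
            state_symbol=str(i + 1),
            label=f"trait{i + 1}",
            support=frozenset(sup),
        )
        for i, sup in enumerate(supports)
    )
    return TraitMatrix(tuple(taxa), traits)


def small_random_matrix(seed, max_taxa=8, max_chars=6):
    """A random CharacterMatrix with dimensions drawn from the seed."""
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        n_taxa=int(rng.integers(2, max_taxa + 1)),
        n_characters=int(rng.integers(1, max_chars + 1)),
        n_states=int(rng.integers(2, 4)),
        missing_rate=float(rng.choice([0.0, 0.1])),
        seed=int(rng.integers(0, 2**31)),
    )
    return random_matrix(cfg)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_relation(a, b):
    """Classify two supports by testing the four set predicates independently."""
    a, b = set(a), set(b)
    assert a and b
    results = []
    if a == b:
        results.append(("I", None))
    if a < b:
        results.append(("II", "AB"))
    if b < a:
        results.append(("II", "BA"))
    if not (a & b):
        results.append(("IV", None))
    if (a & b) and (a - b) and (b - a):
        results.append(("III", None))
    assert len(results) == 1, "predicates must be mutually exclusive"
    return results[0]


def brute_edges(tm: TraitMatrix):
    """All four edge sets by pairwise set comparison (node_id pairs)."""
    edges = {"I": set(), "II": set(), "III": set(), "IV": set()}
    for t1, t2 in combinations(tm.traits, 2):
        if t1.character_id == t2.character_id:
            continue
        etype, direction = brute_relation(t1.support, t2.support)
        if etype == "II":
            pair = (
                (t1.node_id, t2.node_id)
                if direction == "AB"
                else (t2.node_id, t1.node_id)
            )
        else:
            pair = (min(t1.node_id, t2.node_id), max(t1.node_id, t2.node_id))
        edges[etype].add(pair)
    return edges


def brute_triangles(edges_iii, n):
    return sum(
        1
        for a, b, c in combinations(range(1, n + 1), 3)
        if {tuple(sorted(p)) for p in ((a, b), (b, c), (a, c))} <= set(edges_iii)
    )


def brute_d_triplets(edges_iii, edges_iv, n):
    """Per-node type D centrality by enumerating all (t, {s, u})."""
    e3 = {tuple(sorted(p)) for p in edges_iii}
    e4 = {tuple(sorted(p)) for p in edges_iv}
    cent = {i: 0 for i in range(1, n + 1)}
    for t in range(1, n + 1):
        for s, u in combinations(range(1, n + 1), 2):
            if t in (s, u):
                continue
            if (
                tuple(sorted((t, s))) in e3
                and tuple(sorted((t, u))) in e3
                and tuple(sorted((s, u))) in e4
            ):
                cent[t] += 1
    return cent
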