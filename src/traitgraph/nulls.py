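"""Permutation nulls for trait-network statistics.

Two null models are provided, both operating column-by-column on the
character matrix and both preserving each column's state multiset exactly
(so every trait keeps its support *size* and stays identifiable across
replicates by its (character, state) key):

* **equiprobable** — each column receives an independent uniform random
  permutation of its cells, destroying all phylogenetic structure;
* **phylogenetic** — a restricted permutation in which states move
  preferentially between phylogenetically close taxa.  With patristic
  distances d normalized to max 1, taxon pairs are weighted w = k − d
  (k > 1, default 1.01); each column's bijection is drawn by visiting target
  taxa in random order and sampling an unused source taxon with probability
  proportional to its weight.

Empirical one-sided p-values use the add-one convention p = (b + 1)/(M + 1),
where b counts replicates at least as extreme as the observed value, so the
smallest attainable p is 1/(M + 1).  Family-wise error is controlled by
Bonferroni multiplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .matrix import (
    CharacterMatrix,
    TraitMatrix,
    default_absence_matcher,
    recode,
)
from .metrics import DegreeRecord, TripletRecord, find_complexes
from .network import MultiplexTraitNetwork, build_network
from .phylo import TreeModel

__all__ = [
    "NullResult",
    "PhyloWeights",
    "permute_equiprobable",
    "patristic_weights",
    "permute_phylogenetic",
    "null_distribution",
    "bonferroni",
    "significant_stable_traits",
    "significant_pivotal_traits",
    "STANDARD_STATISTICS",
    "NODE_STATISTICS",
]

#: A network statistic: maps a built network to a scalar or per-node vector.
NetworkStatistic = Callable[[MultiplexTraitNetwork], "float | np.ndarray"]


@dataclass
class NullResult:
    """Observed value, permutation replicates and empirical p-values."""

    name: str
    observed: "float | np.ndarray"
    replicates: np.ndarray  # (M_eff,) or (M_eff, N)
    model: str
    M: int  # requested permutation count
    seed: int

    @property
    def M_eff(self) -> int:
        """Replicates actually evaluated (failures reduce M)."""
        return self.replicates.shape[0]

    @property
    def p_high(self) -> "float | np.ndarray":
        b = (self.replicates >= np.asarray(self.observed)).sum(axis=0)
        p = (b + 1) / (self.M_eff + 1)
        return float(p) if np.ndim(self.observed) == 0 else p

    @property
    def p_low(self) -> "float | np.ndarray":
        b = (self.replicates <= np.asarray(self.observed)).sum(axis=0)
        p = (b + 1) / (self.M_eff + 1)
        return float(p) if np.ndim(self.observed) == 0 else p

    def direction(self, alpha: float = 0.05, n_tests: int = 1) -> str:
        """Two-sided verdict label: 'Higher', 'Lower' or 'NS' (scalars only)."""
        ph, pl = self.p_high, self.p_low
        p, label = (ph, "Higher") if ph <= pl else (pl, "Lower")
        return label if bonferroni(p, n_tests) <= alpha else "NS"


@dataclass
class PhyloWeights:
    """Taxon-pair weights w = k − d for the restricted permutation.

    d is the patristic distance matrix normalized to max 1, so all weights
    lie in (k − 1, k] and are strictly positive for k > 1; the diagonal
    weight is exactly k (a state may stay on its own taxon).
    """

    taxa: tuple[str, ...]
    W: np.ndarray
    k: float

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (len(self.taxa),) * 2:
            raise ValueError("weight matrix shape does not match taxa")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(self.W <= 0):
            raise ValueError("weights must be strictly positive (need k > 1)")


def permute_equiprobable(
    cm: CharacterMatrix, rng: np.random.Generator
) -> CharacterMatrix:
    """Uniformly permute each column's cells (missing included) independently."""
    cells = cm.cells.copy()
    n = cm.n_taxa
    for j in range(cm.n_characters):
        cells[:, j] = cells[rng.permutation(n), j]
    return cm.with_cells(cells)


def patristic_weights(
    tree: TreeModel, taxa: Sequence[str], k: float = 1.01
) -> PhyloWeights:
    """Build w = k − d weights from a tree's patristic distances.

    Distances are divided by their maximum so d ∈ [0, 1]; a zero-length tree
    (all distances 0) degenerates to uniform weights with a warning.
    """
    if k <= 1:
        raise ValueError("k must be > 1 so that all weights stay positive")
    taxa = tuple(taxa)
    d = tree.patristic_matrix(taxa)
    dmax = d.max()
    if dmax == 0:
        warnings.warn("all patristic distances are zero; weights are uniform")
    else:
        d = d / dmax
    return PhyloWeights(taxa, k - d, k)


def _sample_restricted_bijections(
    W: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_draws`` independent restricted bijections (rows: perm[target]=source).

    Sequential weighted assignment without replacement: targets are visited
    in random order; each draws a still-unused source with probability
    proportional to W[target, source].  Vectorized across draws.
    """
    T = W.shape[0]
    B = n_draws
    orders = np.argsort(rng.random((B, T)), axis=1)
    remaining = np.ones((B, T), dtype=bool)
    perm = np.empty((B, T), dtype=np.int64)
    rows = np.arange(B)
    for step in range(T):
        targets = orders[:, step]
        w = W[targets] * remaining
        cum = np.cumsum(w, axis=1)
        u = rng.random(B) * cum[:, -1]
        src = np.minimum((cum <= u[:, None]).sum(axis=1), T - 1)
        perm[rows, targets] = src
        remaining[rows, src] = False
    return perm


def permute_phylogenetic(
    cm: CharacterMatrix, weights: PhyloWeights, rng: np.random.Generator
) -> CharacterMatrix:
    """Phylogenetically restricted within-column permutation.

    Each column independently receives a random bijection π of taxa drawn
    under ``weights`` (taxon order must match the matrix); taxon i is then
    assigned taxon π(i)'s original state, preserving the column's state
    multiset exactly.
    """
    if tuple(weights.taxa) != tuple(cm.taxa):
        raise ValueError("weights taxa do not match matrix taxa")
    perms = _sample_restricted_bijections(weights.W, cm.n_characters, rng)
    cells = cm.cells.copy()
    for j in range(cm.n_characters):
        cells[:, j] = cm.cells[perms[j], j]
    return cm.with_cells(cells)


# ---------------------------------------------------------------------------
# standard statistics
# ---------------------------------------------------------------------------


#: Scalar statistics of the kind reported in the summary table.
STANDARD_STATISTICS: Mapping[str, NetworkStatistic] = {
    "n_complexes": lambda net: float(len(find_complexes(net))),
    "n_edges_I": lambda net: float(net.edge_counts()["I"]),
    "n_edges_II": lambda net: float(net.edge_counts()["II"]),
    "n_edges_III": lambda net: float(net.edge_counts()["III"]),
    "n_edges_IV": lambda net: float(net.edge_counts()["IV"]),
    "n_triangles_III": lambda net: float(net.triangle_count_III),
    "proportion_triangles_III": lambda net: net.triangle_count_III
    / (net.n_nodes * (net.n_nodes - 1) * (net.n_nodes - 2) / 6.0),
    "density_III": lambda net: 2.0
    * net.edge_counts()["III"]
    / (net.n_nodes * (net.n_nodes - 1)),
    "n_typeD": lambda net: float(net.d_centrality.sum()),
}

#: Per-node statistics (return one value per node, in node_id order).
NODE_STATISTICS: Mapping[str, NetworkStatistic] = {
    "in_degree_II": lambda net: net.adj_II.sum(axis=0).astype(float),
    "d_centrality": lambda net: net.d_centrality.astype(float),
}


def _silent_recode(cm, absence_matcher, min_taxa) -> TraitMatrix:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return recode(cm, absence_matcher, min_taxa=min_taxa)


def null_distribution(
    cm: CharacterMatrix,
    model: str,
    M: int,
    statistics: Mapping[str, NetworkStatistic],
    seed: int,
    *,
    absence_matcher=default_absence_matcher,
    min_taxa: int = 1,
    weights: PhyloWeights | None = None,
) -> dict[str, NullResult]:
    """Null distributions of several statistics from one permutation stream.

    For each of the M replicates the matrix is permuted under ``model``
    ("equiprobable" or "phylogenetic"), recoded with the same settings as
    the observed analysis, rebuilt into a network, and every statistic
    evaluated on it — so all statistics share the same replicates.  Because
    both schemes preserve support sizes, the permuted trait set has the same
    (character, state) keys in the same order as the observed one; this is
    asserted on every replicate.  A statistic failure on one replicate
    drops that replicate (with a warning), reducing M.
    """
    if M < 1:
        raise ValueError("M must be ≥ 1")
    if model == "phylogenetic" and weights is None:
        raise ValueError("phylogenetic model requires PhyloWeights (a tree)")
    if model not in ("equiprobable", "phylogenetic"):
        raise ValueError(f"unknown null model {model!r}")

    rng = np.random.default_rng(seed)
    tm0 = _silent_recode(cm, absence_matcher, min_taxa)
    net0 = build_network(tm0)
    keys0 = [(tr.character_id, tr.state_symbol) for tr in tm0.traits]
    observed = {name: f(net0) for name, f in statistics.items()}

    reps: dict[str, list] = {name: [] for name in statistics}
    for _ in range(M):
        if model == "equiprobable":
            pcm = permute_equiprobable(cm, rng)
        else:
            pcm = permute_phylogenetic(cm, weights, rng)
        try:
            tm = _silent_recode(pcm, absence_matcher, min_taxa)
            keys = [(tr.character_id, tr.state_symbol) for tr in tm.traits]
            if keys != keys0:
                raise AssertionError(
                    "permutation altered the trait set; support sizes "
                    "should be invariant"
                )
            net = build_network(tm)
            vals = {name: f(net) for name, f in statistics.items()}
        except AssertionError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"replicate dropped ({exc}); M effectively reduced")
            continue
        for name, v in vals.items():
            reps[name].append(v)

    return {
        name: NullResult(
            name=name,
            observed=observed[name],
            replicates=np.asarray(reps[name]),
            model=model,
            M=M,
            seed=seed,
        )
        for name in statistics
    }


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p · n_tests)."""
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be ≥ 1")
    return min(1.0, p * n_tests)


def check_permutation_count(M: int, n_tests: int, alpha: float) -> bool:
    """True if M permutations can reach Bonferroni-corrected significance.

    The smallest attainable corrected p is n_tests/(M + 1), so corrected
    significance at level alpha requires M ≥ n_tests/alpha − 1.
    """
    ok = M >= n_tests / alpha - 1
    if not ok:
        warnings.warn(
            f"M={M} permutations cannot reach corrected significance at "
            f"alpha={alpha} over {n_tests} tests (need M ≥ "
            f"{int(np.ceil(n_tests / alpha - 1))})"
        )
    return ok


def _flag_significant(
    null_equi: NullResult, null_phylo: NullResult, alpha: float
) -> set[int]:
    n = np.asarray(null_equi.observed).shape[0]
    for null in (null_equi, null_phylo):
        if np.asarray(null.observed).shape[0] != n:
            raise ValueError("null results cover different node sets")
    flagged = set()
    pe, pp = null_equi.p_high, null_phylo.p_high
    for i in range(n):
        if (
            bonferroni(float(pe[i]), n) <= alpha
            and bonferroni(float(pp[i]), n) <= alpha
        ):
            flagged.add(i + 1)
    return flagged


def significant_stable_traits(
    records: Sequence[DegreeRecord],
    null_equi: NullResult,
    null_phylo: NullResult | None,
    alpha: float = 0.05,
) -> set[int]:
    """Nodes whose type II in-degree is upper-tail significant under *both* nulls.

    p-values are Bonferroni-corrected over the family of all N nodes; a node
    qualifies only if its corrected upper-tail p ≤ alpha under the
    equiprobable AND the phylogenetic model.
    """
    if null_phylo is None:
        raise ValueError("stability calls require the phylogenetic null (a tree)")
    flagged = _flag_significant(null_equi, null_phylo, alpha)
    in_deg = {r.node_id: r.in_degree for r in records}
    return {i for i in flagged if in_deg[i] > 0}


def significant_pivotal_traits(
    records: Sequence[TripletRecord],
    null_equi: NullResult,
    null_phylo: NullResult | None,
    alpha: float = 0.05,
) -> set[int]:
    """Nodes significantly overrepresented as type D triplet centers (both nulls)."""
    if null_phylo is None:
        raise ValueError("pivotality calls require the phylogenetic null (a tree)")
    flagged = _flag_significant(null_equi, null_phylo, alpha)
    cent = {r.node_id: r.d_centrality for r in records}
    return {i for i in flagged if cent[i] > 0}
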