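# traitgraph

Multiplex trait co-occurrence networks from morphological character
matrices, with equiprobable and phylogenetically restricted permutation
tests.

## What problem this solves

Morphological phylogenetics scores organisms in a characters × taxa matrix
and asks what tree it supports. `traitgraph` asks a complementary,
tree-free question of the same matrix: **how do individual character
states (traits) co-occur across taxa?** Every non-absence state of every
character becomes a node ("trait") supported by the set of taxa bearing
it, and every pair of traits from *different* characters falls into
exactly one of four relations, decided by set algebra on their supports:

| type | relation between supports | reading |
|------|---------------------------|---------|
| I    | identical                 | the traits always co-occur ("complexes" — candidate common regulation or common ancestry) |
| II   | strictly nested (directed nested → inclusive) | relative stability: the inclusive trait is a backbone the nested one presupposes |
| III  | overlapping, non-nested   | dissociability: the traits are combined in some taxa and decoupled in others |
| IV   | disjoint                  | the traits are never found together |

On the type II layer, a trait's **in-degree** counts how many traits have
supports nested inside its own (high = stable backbone trait; in-degree 0
with positive out-degree = precarious/unstable). On the type III layer,
with k edges over N traits, the package computes the density 2k/(N(N−1)),
the triangle count, the triangle proportion (triangles divided by *all*
N(N−1)(N−2)/6 possible triples — deliberately not transitivity), and the
diameter. A **type D triplet** {s, t, u} has t–s and t–u overlapping
(type III) and s–u disjoint (type IV): t is a *pivotal* candidate, a trait
reused in alternative body organizations that never co-occur.

Whether any of this exceeds chance is assessed by column-wise permutation
nulls that preserve each character's state multiset: an **equiprobable**
null (free within-column shuffling) and a **phylogenetic** null in which
states move preferentially between close relatives, with taxon-pair
weights w = k − d (d the patristic distance normalized to max 1, default
k = 1.01). Empirical one-sided p-values use p = (b+1)/(M+1) and are
Bonferroni-corrected; per-node stability/pivotality calls require
significance under *both* nulls.

## Worked example

```python
from traitgraph import build_network, count_d_triplets, pivotal_motif_fixture, summarize

tm, ids = pivotal_motif_fixture()        # four traits over taxa {a..e}
net = build_network(tm)
rep = summarize(net)
```

prints (via `python examples/02_network_metrics.py`):

```
edge counts: {'I': 0, 'II': 0, 'III': 4, 'IV': 2}
type III density  = 0.6667  (2k/(N(N-1)), N=4)
triangle count    = 1
triangle fraction = 0.25 (triangles / all possible triples)
diameter          = 2

2 type D triplets; trait '38' is central in 2 of them -> pivotal candidate
```

Four overlap edges and two disjoint edges make trait "38" the center of
two type D triplets: it is combined with partners ("43" vs "2"/"12") that
never occur together — the signature of a pivotal trait. The other
example scripts cover recoding (`01`), permutation testing (`03`),
comparison of nested pairs against a reference tree (`04`), and the full
end-to-end pipeline on a simulated 21 × 120 matrix (`05`).

A thin CLI wraps the same pipeline:

```sh
traitgraph simulate --taxa 21 --characters 120 --seed 1 --out m.nex
traitgraph run --matrix m.nex --permutations 5000 --seed 1 --out results/
```

writing `traits.tsv`, `edges_type1..4.tsv`, `multiplex.graphml`,
`nodes.tsv`, `complexes.tsv`, `permutations.tsv`, `nested_pairs.tsv` (with
`--tree`), and `summary.json`.

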