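"""Permutation nulls: is the network structure explainable by chance?

A matrix is simulated with phylogenetic signal on a two-clade tree, then
its type I (identical-support) edge count is tested against the
equiprobable null (columns shuffled freely) and the phylogenetically
restricted null (states move preferentially between close relatives,
weights k − d with k = 1.01).
"""

from traitgraph import (
    STANDARD_STATISTICS,
    SimulationConfig,
    null_distribution,
    parse_newick,
    patristic_weights,
    simulate_mk_on_tree,
)

tree = parse_newick("((a:.2,b:.2,c:.2):2,(d:.2,e:.2,f:.2):2);")
cfg = SimulationConfig(n_taxa=6, n_characters=60, n_states=2, rate=0.4, seed=4)
cm = simulate_mk_on_tree(cfg, tree)

stats = {name: STANDARD_STATISTICS[name] for name in ("n_edges_I", "n_edges_III")}
M = 999
equi = null_distribution(cm, "equiprobable", M, stats, seed=1)
w = patristic_weights(tree, cm.taxa, k=1.01)
phylo = null_distribution(cm, "phylogenetic", M, stats, seed=2, weights=w)

for name in stats:
    e, p = equi[name], phylo[name]
    print(f"{name}: observed {e.observed:.0f}")
    print(f"  equiprobable null : p_high {e.p_high:.4f} p_low {e.p_low:.4f}")
    print(f"  phylogenetic null : p_high {p.p_high:.4f} p_low {p.p_low:.4f}")
print(f"\n(min attainable p is 1/(M+1) = {1/(M+1):.6f})")
print("Identical-support pairs exceed the equiprobable expectation because "
      "clade-mates share states; the restricted null absorbs part of that "
      "signal, so its p is less extreme.")
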