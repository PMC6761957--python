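"""Compare nested trait pairs against a reference phylogeny.

Every type II (nested-support) edge is classified by whether its inner and
outer supports are clades of the reference tree: nested clades read as
nested synapomorphies, anything else points to convergence, loss, or
missing sampling.
"""

from traitgraph import build_network, classify_nested_pairs, parse_newick
from traitgraph.matrix import Trait, TraitMatrix

tree = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")

supports = [
    {"A"},                      # nested in the AB clade trait
    {"A", "B"},                 # a clade
    {"A", "B", "C"},            # a clade
    {"A", "C", "D"},            # not a clade
]
traits = tuple(
    Trait(i + 1, i + 1, "1", f"trait{i + 1}", frozenset(s))
    for i, s in enumerate(supports)
)
tm = TraitMatrix(("A", "B", "C", "D", "E"), traits)
net = build_network(tm)

counts, rows = classify_nested_pairs(net, tree)
print(f"{net.edge_counts()['II']} nested (type II) trait pairs:")
for inner, outer, mi, mo, cls in rows:
    print(f"  {set(supports[inner-1])} within {set(supports[outer-1])}: {cls}")
print("\nclass totals:", {k: v for k, v in counts.items() if v})
print("Only clade_in_clade pairs behave like nested synapomorphies; the "
      "others need extra processes (convergence, loss) to explain.")
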