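# Methods

## Recoding a character matrix into traits

The input is a taxa × characters matrix of discrete state symbols, with a
single missing token (`?`). Each character is split into one
presence/absence column per state; states whose *label* indicates absence
are discarded (default matcher: case-insensitive `/absen/`; explicit
symbols or labels can be supplied per run, and with no labels and no
option nothing is treated as absence). Each retained (character, state)
pair whose support — the taxa scored with that state — has at least
`min_taxa` members becomes a trait, ordered by (character id, declared
state order) and numbered 1..N. The default `min_taxa = 1` keeps
single-taxon traits; users wanting to exclude autapomorphy-like traits can
raise it.

Missing cells contribute to no trait's support — i.e., a taxon with a
missing score behaves as if it lacked all of that character's states. This
is the only missing-data policy implemented; it is logged whenever it
fires, and it matters little for matrices as complete as the motivating
data (a single missing cell). Polymorphic cells, gap/missing distinctions
and continuous characters are out of scope.

Recoding is lossless for non-missing, non-absence content: per character,
the union of trait supports equals the set of taxa with a non-missing,
non-absence score (a property test asserts this).

## The four relations and the multiplex network

For every pair of traits from different characters, with supports A and B
(both non-empty by construction):

* A = B → **type I** (undirected);
* A ⊊ B → **type II**, a directed edge A → B from the nested to the
  inclusive trait (B ⊊ A gives the reverse edge);
* A ∩ B = ∅ → **type IV** (undirected);
* otherwise → **type III** (undirected overlap).

Equal supports are type I only — type II is strict nesting, so the four
cases partition all comparable pairs, which is asserted as an invariant
(Σ|edges| = C(N,2) − Σ_c C(n_c,2), n_c the trait count of character c).
Same-character pairs get no edge of any type: two states of one character
have disjoint supports by construction, and connecting them would only
restate the coding. Strict nesting is a partial order, so the type II
layer is acyclic.

Internally the network stores one boolean adjacency matrix per layer,
computed from the N × T incidence matrix by one integer matrix product
(|A ∩ B| for all pairs at once); the public edge-set views, the GraphML
export and the per-layer networkx graphs are derived lazily from those
matrices. This single implementation serves both the user-facing API and
the permutation machinery, which rebuilds the network thousands of times.
Matrix products run in float64 (exact for counts far below 2^53) to stay
inside BLAS.

## Network statistics

* **Complexes** — connected components (≥2 nodes) of the type I layer.
  Identity of supports is transitive, so each component must be a clique;
  this is verified rather than assumed. Sorted by (size, lowest node id).
* **Stability degrees** — type II in/out degree per node; in-degree 0 with
  out-degree > 0 flags a precarious (unstable) trait, positive in-degree a
  relatively stable one.
* **Type III statistics** — edge count k; density 2k/(N(N−1)); triangle
  count (trace(A³)/6); triangle proportion = triangles / (N(N−1)(N−2)/6).
  The denominator counts *all* unordered triples, so the proportion is
  deliberately smaller than a transitivity/clustering coefficient, which
  divides by connected triads only — do not substitute one for the other.
  N is always the total trait count, including nodes isolated in the type
  III layer, so that density and proportion are reproducible from a single
  consistent N. The diameter of a disconnected layer is the largest finite
  eccentricity over its components (single nodes contribute 0); component
  sizes are available from the layer graph. Density requires N ≥ 2 and the
  proportion N ≥ 3; smaller networks raise.
* **Type D triplets** — unordered triples {s, t, u} with t–s, t–u of type
  III and s–u of type IV; t is the central node. Per-node centrality is
  ½·diag(A₃A₄A₃), and the total over nodes equals the triplet count (each
  triplet has exactly one center). Brute-force enumeration over all
  triples is the test oracle for both triangles and type D counts.

## Permutation nulls

Both nulls permute each column independently and preserve its state
multiset exactly, so every trait keeps its support *size* and remains
identifiable by (character, state) across replicates — the permuted trait
set is checked to be identical, and all statistics of one model share one
replicate stream.

* **Equiprobable**: a uniform random permutation per column, destroying
  all phylogenetic structure.
* **Phylogenetic (restricted)**: patristic leaf distances are normalized
  to max 1, and taxon pairs weighted w = k − d with k > 1 (default 1.01,
  diagonal weight exactly k). Each column's bijection is drawn by visiting
  target taxa in random order and sampling a still-unused source taxon
  with probability proportional to w(target, source) — sequential weighted
  assignment without replacement, vectorized across columns. Trees without
  branch lengths get unit lengths (with a warning); a zero-length tree
  degenerates to uniform weights.

One property of this weight law deserves emphasis: because the diagonal is
k and every other taxon on a *star* tree sits at the maximal normalized
distance 1, small k favors leaving states in place on a star tree rather
than permuting them uniformly. The restricted null coincides with the
equiprobable null only in the exchangeable limit — large k, where all
weights converge — and the equivalence tests are run in that regime. At
the default k = 1.01 on a structured tree the intended behavior holds:
states exchange readily within tight clades and rarely across deep
splits (a unit test demonstrates both effects).

Empirical one-sided p-values use the add-one convention p = (b+1)/(M+1),
b the number of replicates at least as extreme as the observed value in
the given direction; the smallest attainable p is therefore 1/(M+1), and
scalar statistics report the smaller tail with a Higher/Lower/NS label
after Bonferroni correction over the scalar family. Per-node tests
(stability = type II in-degree, pivotality = type D centrality) use the
upper tail only, Bonferroni-corrected over all N nodes, and a node is
called significant only under *both* nulls. The default M = 5000 gives
the floor 1/5001 ≈ 0.0002; a startup check warns when M < n_tests/α − 1,
i.e. when corrected significance is unattainable by construction. p-value
calibration (super-uniformity under data generated from the equiprobable
null itself) is covered by a 500-dataset KS test in the acceptance suite.

## Reference-tree comparison

Monophyly of a taxon set is "some node of the rooted tree subtends exactly
this set"; singletons and the full leaf set count as monophyletic, and
"paraphyletic" here simply means *not monophyletic with respect to the
sampled taxa* (no para/polyphyletic distinction — the tree is used as
rooted, with no unrooted-bipartition fallback). Every type II edge is
classified by the (inner, outer) monophyly pair into clade-in-clade,
clade-in-paraphyletic, paraphyletic-in-clade, or
paraphyletic-in-paraphyletic; the four counts always sum to |edges II|.
Nested clades read as nested synapomorphies; everything else requires
additional processes (convergence, loss, incomplete sampling).

## Synthetic data

`random_matrix` draws iid uniform states per cell with an optional missing
rate — exactly the world of the equiprobable null, which is what makes it
the right substrate for calibration tests. `simulate_mk_on_tree` evolves
each character independently along a given tree under the symmetric
q-state Mk process (uniform root, exact matrix exponential per branch —
cheap at small q and fully reproducible, no event-by-event simulation),
producing the phylogenetic autocorrelation the restricted null is meant to
respect. Neither generator models correlated characters, gamma rate
heterogeneity, or deliberate planting of complexes; passing tests on these
generators therefore demonstrate correctness of the graph and permutation
machinery, not that real morphological matrices behave like either
generator.

Default dimensions follow the motivating study: 21 taxa × 120 characters.
Study-scale runs that exercise the per-node significance machinery use
binary characters, keeping the trait count near the study's N = 213 (of a
possible 240); with more states per character N grows past the point where
the Bonferroni floor N/(M+1) exceeds α = 0.05 at M = 5000 and per-node
significance becomes unattainable by construction.

The worked fixture (`pivotal_motif_fixture`) hand-builds four traits over five taxa
with supports {a,b}, {b,c,d}, {c,e}, {d,e}: four type III edges, two type
IV edges, one triangle, diameter 2, and one node central in exactly two
type D triplets.

## Numerical and design notes

* Node ids are 1-based in matrix order (character, then declared state
  order); a mapping table (`traits.tsv`) aligns them with any external
  numbering.
* Undirected edges are stored keyed (low id, high id); all iteration
  orders are deterministic, and a rerun with identical settings and seed
  reproduces every output byte-for-byte.
* The type D motif is defined on the type III + type IV layers (two
  overlap edges through the center, one disjoint edge across), which is
  the definition used consistently throughout.
* The Fisher regionalization test builds a 2×2 table of unstable
  (in-degree 0) versus other traits across two body-region groups —
  default split: cranio-dental (skull, teeth, jaw) versus postcranial
  (body plan, forelimb, hind limb) — and reports the two-sided exact
  hypergeometric p (scipy); an empty margin returns p = 1 with a warning.
* The exact reproduction of the published ceratomorph statistics requires
  the original data deposit, which cannot be redistributed here; the
  repository instead carries the deposit-free cross-check that the printed
  density and triangle-proportion identities jointly pin the trait count
  (N = 213), which any recode of the deposit must match.

## Known limitations

* No polymorphic cells, no continuous characters, no weighted relations.
* One missing-data policy (missing = absent for that character).
* The restricted-permutation sampler is a sequential-assignment scheme
  consistent with the w = k − d weight law; other samplers consistent with
  the same law exist and may differ in higher-order properties.
* Reported per-node significance depends on M through the Bonferroni
  floor; raise M together with N.
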