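# Methods

## Definitions and conventions

A tree is a connected acyclic graph; leaves are degree-1 nodes. A rooted
tree distinguishes one node of degree ≥ 2 as root. Internal nodes are
non-leaves, excluding the root. Internal edges touch no leaf; m counts them,
k counts degree-2 internal nodes. A tree is *proper* when k = 0 and every
internal node has degree ≥ 3 (the root needs only degree 2). A phylogenetic
tree attaches a bijection between leaves and labels {1..n}; external taxon
names are kept in a side map and bound to labels in lexicographic name
order, so two Newick files over the same taxa align automatically.

Cutting an internal edge of an unrooted tree induces a bipartition of the
label set; the non-trivial ones (both sides ≥ 2) form P(T). Each internal
node of a rooted tree induces the cluster of labels below it; the
non-trivial ones (size in [2, n−1]) form Cl(T). All edges along a degree-2
chain induce the same bipartition (and every node of the chain the same
cluster), so P and Cl are sets, |P(T)| = m − k, and collapsing each maximal
degree-2 chain to a single edge (`suppress_degree_two`) leaves P and Cl
unchanged. The distances are symmetric-difference counts: `tpd` on
bipartitions (unrooted), `cd` on clusters (rooted), and `urcd(T1, T2)` =
min over every edge e of T1 — leaf edges included — of `cd` between T1
rooted on e and T2.

## The exact worst-case bound

For fixed shapes, the maximum of tpd/cd over all label assignments is

    w(T1, T2) = (m1 − k1) + (m2 − k2).

Upper bound: each internal edge contributes at most one bipartition and
degree-2 chains merge, so |P(Ti)| = mi − ki and the symmetric difference is
at most their sum. Tightness is constructive (`construct_unrooted`,
`construct_rooted`): an induction on n over the degree-2-suppressed shapes.

* base n = 3: unrooted shapes are stars (w = 0, any labeling); rooted
  shapes are the star or a cherry — when both trees have a cherry, the
  cherries get labels {1,2} and {1,3}, which differ.
* case 1 — one tree is a star: its split set is empty under every labeling,
  so any labeling works.
* case 2 — both trees have an internal node holding ≥ 3 leaves: delete one
  such leaf from each, solve for n−1, give label n to both deleted leaves.
  Splits that differed still differ after inserting n, and no new collision
  appears.
* case 3 — some tree has every internal node holding ≤ 2 leaves: it then
  contains a *cherry* node u of degree 3 with leaves u1, u2 and one
  internal (or root) neighbour v. Contract u into v (removing leaf u1). If
  the other tree has a ≥ 3-leaf node, delete a leaf x1 there; otherwise
  contract a cherry x (leaves x1, x2, neighbour y) there too and, after
  solving for n−1, repair any collision between the two new cherry splits
  {n, label(u2)} and {n, label(x2)}: swap label(u2) (or label(x2)) with a
  sibling leaf under v (or y) when one exists — leaves on the same node are
  interchangeable, so the recursive distance is untouched — and in the
  doubly-constrained subcase exchange labels n and the smallest k ≠ i in
  the first tree only.

Every "choose a node/leaf" step picks the smallest node id, making the
output deterministic. The subcase facts (how many leaves v and y hold)
refer to the contracted (n−1)-leaf trees and are snapshotted before the
recursive call, which further mutates the working copies. Improper inputs
are suppressed first; suppression touches no leaf, so the constructed
labeling transfers back verbatim, and the achieved distance equals the
discounted bound. Construction is O(n) levels of O(n) work plus a final
O(n²)-ish verification; pairs with n in the hundreds are instantaneous.

Every construction re-scores its own output and raises on any mismatch for
tpd/cd; this is an internal-bug signal, not an expected path.

## The unrooted-vs-rooted case

Rooting an n-leaf unrooted tree on any edge subdivides it with a new root;
every internal node survives and none is created *as an internal node*
(the root is exempt) — but the rooted tree has one more internal edge than
the unrooted one had (m+1 internal nodes each owning one parent edge). The
closed form above therefore does not transfer exactly to `urcd`.
`exact_bound(..., mode="urcd")` still reports (m1−k1)+(m2−k2);
`construct_urcd` roots T1 on its smallest edge, runs the rooted
construction, transfers the labeling back, and reports the genuine
min-over-all-rootings distance as `achieved`, with a logged diagnostic and
a `bound_attained` flag instead of an assertion.

The exhaustive oracle (all shape pairs, n = 3..5; plus random pairs up to
n = 64) shows the true max-over-labelings of d_ur deviates from the formula
by exactly ±1 in this range: +1 when the extra internal node survives the
minimization (e.g. two 3-leaf stars: every rooting of a star yields exactly
one non-trivial cluster, so d_ur = 1 while the formula gives 0), and −1
when every labeling admits a rooting that matches a cluster (e.g. unrooted
star vs rooted cherry: rooting on the non-cherry taxon's leaf edge always
reproduces the cherry, d_ur = 0, formula 1). In every exhaustively checked
case the constructed labelings attain the true maximum. These statements
are recomputed by `tests/test_acceptance.py`, not asserted from memory.

## Normalization

`normalized` returns raw/w as an exact `Fraction`; when w = raw = 0 (two
stars) the value is 0 by convention — the trees are indistinguishable at
the split level, and continuity with raw distance 0 argues for 0 rather
than an error. For urcd the raw value can exceed a zero formula bound (see
above); that corner returns value 1 with a log notice. `classic_normalized`
divides by 2n−6 and refuses n = 3 (zero divisor). `randomized_bound`
reproduces the older approximation of w: the maximum distance over `reps`
uniform relabelings of the second tree. Each rep's permutation is derived
from `Random(f"{seed}:{rep}")`, a counter-based scheme, so the estimate for
larger `reps` extends rather than replays smaller ones (monotone in reps
for a fixed seed). It never exceeds w and can fall strictly short at small
`reps` — the motivation for the exact formula.

## Generators and the oracle

`random_topology(n, rooted, resolution, k, seed)` grows a uniform random
binary shape by sequential leaf attachment to a uniformly chosen edge, then
contracts round((1−resolution)·m_binary) randomly chosen internal edges
into multifurcations, then subdivides k uniformly chosen edges (leaf edges
included — a degree-2 node is legal anywhere). Defaults: resolution 1
(fully resolved), k 0 (proper), matching the shapes users feed the tool in
practice; everything is deterministic given the seed. The generator
emulates tree *shapes* only — there are no branch lengths and no model of
character evolution — so tests built on it certify the combinatorial
claims, not anything about inference on real alignments.

`enumerate_topologies` yields one representative per isomorphism class:
proper rooted shapes by recursive multiset composition (every non-leaf ≥ 2
children), proper unrooted shapes by rooting at an internal node (≥ 3
children at the top) and deduplicating with an AHU canonical string
minimized over rootings; improper variants by bounded edge subdivision.
The default cap n ≤ 7 keeps class counts desk-scale; tests cross-check the
counts against an independent filter over `networkx.nonisomorphic_trees`.

`brute_force_max` fixes the first tree's labeling — distances are invariant
under relabeling both trees by the same permutation, a property the tests
assert — and scans all n! labelings of the second (cap n ≤ 8, no
automorphism pruning: 8! evaluations is cheap and an oracle should stay
dumb). `sweep` tabulates oracle vs formula vs construction over all ordered
shape pairs; ordered, despite symmetry, to surface asymmetry bugs.

## Problem sizes in the checks

The acceptance-style tests sweep all proper shape pairs at n = 3..6
(unrooted) and n = 3..5 (rooted); degree-2 variants with 1–2 insertions at
n ≤ 5, with the rooted n = 5 improper pool (212 classes) paired against the
12 proper classes rather than against itself; 50 binary pairs with n drawn
from 4..64; 200 pairs for randomized-bound dominance; 500 triples for the
metric axioms. These sizes exercise every code path (all proof cases and
subcases occur by n = 6) while the whole suite stays interactive.

## Newick dialect

Input is standard Newick via dendropy; names may be quoted; branch lengths
are parsed and discarded with a log notice (all metrics are topological);
internal node names are ignored. In unrooted mode the top-level node is an
ordinary node: a top-level bifurcation becomes a degree-2 node that is kept
and reported in k — parsing is lossless, and suppression is an explicit
operation. In rooted mode the top-level node becomes the root and must have
degree ≥ 2. Single-child clauses become degree-2 nodes and survive a
write/read round trip. Unlabeled leaves, duplicate names and n < 3 are
rejected. Output writes unrooted trees from a multifurcating internal node
when one exists; unnamed leaves are written as zero-padded label strings so
round-tripping preserves the labeling exactly.

## Known limitations

* No branch-length-aware metrics (weighted RF, branch score), no networks,
  no partially overlapping taxon sets (label mismatch is an error, not a
  pruning rule).
* The ±1 characterization of the urcd worst case is an empirical statement
  over the exhaustively checked range (all shapes n ≤ 5, random pairs to
  n = 64), not a proved theorem; `construct_urcd` therefore reports rather
  than asserts.
* The oracle's factorial scan and the enumeration caps (n ≤ 8, n ≤ 7) are
  hard limits by design.
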