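# rfbound

Robinson–Foulds tree comparison with **exact, topology-aware worst-case
bounds** — and the constructive leaf labelings that achieve them.

## The problem

The Robinson–Foulds distance is the standard dissimilarity between two
phylogenetic trees on the same taxa: for unrooted trees the *tree partition
distance* d(T₁,T₂) = |P(T₁) △ P(T₂)|, the symmetric difference of the sets of
non-trivial bipartitions induced by internal edges; for rooted trees the
*cluster distance* d_r = |Cl(T₁) △ Cl(T₂)| over non-trivial clusters; and
between an unrooted T₁ and a rooted T₂ the *unrooted cluster distance*
d_ur = min over all rootings T₁,ₑ of d_r(T₁,ₑ, T₂).

To compare distances across studies the raw value must be normalized. The
classical divisor 2n−6 (the global maximum over all n-leaf pairs) ignores the
topologies actually at hand: a star tree can never be 2n−6 away from
anything. The topology-aware normalization divides instead by

    w(T₁,T₂) = (m₁ − k₁) + (m₂ − k₂)

where mᵢ is the number of internal edges of Tᵢ (edges touching no leaf) and
kᵢ its number of degree-2 internal nodes. w is the *exact* worst case of the
distance over every way of assigning the n taxa to the leaves of the two
fixed tree shapes — previously approximated in practice by taking the
maximum over many random relabelings. `rfbound` computes w in closed form,
constructs labelings that provably achieve it, and exposes the randomized
approximation only for comparison.

For d_ur the same formula is reported, with a caveat the package makes
explicit: rooting an n-leaf tree on any edge creates one extra internal
node, so the true achievable maximum of d_ur can be w+1 (typical) or w−1
(when every labeling admits a rooting matching some cluster). The built-in
exhaustive oracle quantifies this on small trees; worst-case constructions
for d_ur report both the formula and the genuinely achieved value.

## What is in the box

| module | contents |
| --- | --- |
| `rfbound.tree_model` | tree structures, Newick I/O (multifurcations and degree-2 nodes preserved), shape statistics (n, m, k), degree-2 suppression, rooting, random and exhaustive topology generation |
| `rfbound.splits` | non-trivial bipartition set P(T) and cluster set Cl(T) |
| `rfbound.distances` | `tpd`, `cd`, `urcd` |
| `rfbound.worst_case` | `exact_bound` (= w), constructive `construct_unrooted` / `construct_rooted` / `construct_urcd`, `verify` |
| `rfbound.normalization` | exact d/w, classic d/(2n−6), randomized max-relabeling bound |
| `rfbound.oracle` | brute-force maxima over all n! labelings (n ≤ 8) and sweep tables |
| `rfbound.cli` | `rfbound` command: `distance`, `bound`, `construct`, `normalize`, `brute`, `simulate` |

## Worked example

Two conflicting 6-taxon bird trees:

```sh
$ cat birds.nwk
((wren,(robin,finch)),(heron,(egret,stork)));
$ cat birds_alt.nwk
(((wren,heron),robin),(finch,(egret,stork)));

$ rfbound distance birds.nwk birds_alt.nwk --mode tpd
4
```

Four bipartitions are unmatched between the two trees. Is that a lot for
these shapes? Ask for the worst case:

```sh
$ rfbound bound birds.nwk birds_alt.nwk
n	6
m1	4
k1	1
m2	4
k2	1
6
```

Each tree has m = 4 internal edges of which k = 1 comes from the degree-2
node introduced by the top-level bifurcation of the Newick string (kept, not
silently suppressed; it never contributes an extra bipartition, hence the
−k). The worst case for these two topologies is w = (4−1)+(4−1) = 6, so the
observed distance normalizes to

```sh
$ rfbound normalize birds.nwk birds_alt.nwk --scheme exact
scheme	exact
raw	4
bound	6
0.6666666666666666
```

i.e. the trees realize two thirds of the maximal possible conflict. A pair
of labelings that actually attains w = 6 (verified by re-scoring):

```sh
$ rfbound construct birds.nwk birds_alt.nwk -o worst
...
achieved=6 bound=6 verified=true
$ cat worst.1.nwk worst.2.nwk
(((t4,(t1,t3))),t5,(t6,t2));
(((t1,(t2,t3))),(t6,t5),t4);
```

On trees this small the exhaustive oracle can confirm the formula directly
(all 6! relabelings):

```sh
$ rfbound brute birds.nwk birds_alt.nwk
6
```

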