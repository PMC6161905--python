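"""Non-trivial bipartitions of unrooted trees and clusters of rooted trees.

Cutting an internal edge of an unrooted tree splits the label set in two
(a bipartition); each internal node of a rooted tree defines the label set
of its subtree (a cluster). Both collections exclude the trivial cases
(singleton sides; the full label set) and are genuine sets: the edges along
a degree-2 chain all induce the same bipartition and contribute it once.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Set

from .tree_model import PhylogeneticTree, TreeStructureError

Cluster = FrozenSet[int]


class Bipartition:
    """Unordered two-set partition of {1..n}; equality ignores side order."""

    __slots__ = ("side1", "side2")

    def __init__(self, side_a, side_b):
        a, b = frozenset(side_a), frozenset(side_b)
        if a & b or not a or not b:
            raise ValueError("sides must be disjoint and non-empty")
        # canonical: side1 holds the smallest label overall
        if min(a) < min(b):
            self.side1, self.side2 = a, b
        else:
            self.side1, self.side2 = b, a

    @property
    def nontrivial(self) -> bool:
        return len(self.side1) >= 2 and len(self.side2) >= 2

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Bipartition)
            and self.side1 == other.side1
            and self.side2 == other.side2
        )

    def __hash__(self) -> int:
        return hash((self.side1, self.side2))

    def __repr__(self) -> str:
        fmt = lambda s: ",".join(map(str, sorted(s)))  # noqa: E731
        return f"{{{fmt(self.side1)}}}|{{{fmt(self.side2)}}}"


def is_nontrivial_cluster(c: Cluster, n: int) -> bool:
    return 2 <= len(c) <= n - 1


def _labels_on_side(tree: PhylogeneticTree, start: int, blocked: int) -> Set[int]:
    """Leaf labels reachable from ``start`` without crossing ``blocked``."""
    topo = tree.topology
    seen = {blocked, start}
    stack = [start]
    labels: Set[int] = set()
    if topo.is_leaf(start):
        labels.add(tree.labeling[start])
    while stack:
        v = stack.pop()
        for w in topo.adj[v]:
            if w in seen:
                continue
            seen.add(w)
            if topo.is_leaf(w):
                labels.add(tree.labeling[w])
            else:
                stack.append(w)
    return labels


def bipartitions(tree: PhylogeneticTree) -> Set[Bipartition]:
    """P(T): non-trivial bipartitions of an unrooted phylogenetic tree,
    one per internal edge (duplicates from degree-2 chains merged)."""
    if tree.topology.rooted:
        raise TreeStructureError("bipartitions requires an unrooted tree")
    all_labels = set(tree.labeling.values())
    out: Set[Bipartition] = set()
    for (u, v) in tree.topology.internal_edges():
        side = _labels_on_side(tree, u, blocked=v)
        bp = Bipartition(side, all_labels - side)
        if bp.nontrivial:
            out.add(bp)
    return out


def clusters(tree: PhylogeneticTree) -> Set[Cluster]:
    """Cl(T): non-trivial clusters of a rooted phylogenetic tree, one per
    internal node (root and leaves excluded; duplicates merged)."""
    topo = tree.topology
    if not topo.rooted:
        raise TreeStructureError("clusters requires a rooted tree")
    n = tree.n
    parent = topo.parent_map()
    out: Set[Cluster] = set()
    for v in topo.internal_nodes():
        below = frozenset(_labels_on_side(tree, v, blocked=parent[v]))
        if is_nontrivial_cluster(below, n):
            out.add(below)
    return out


def splits_dump(tree: PhylogeneticTree) -> str:
    """Debug dump: one split per line, tab-separated label lists."""
    if tree.topology.rooted:
        rows = sorted(sorted(c) for c in clusters(tree))
        return "\n".join("\t".join(map(str, row)) for row in rows)
    rows = sorted(
        (sorted(bp.side1), sorted(bp.side2)) for bp in bipartitions(tree)
    )
    return "\n".join(
        "\t".join(map(str, a)) + " | " + "\t".join(map(str, b)) for a, b in rows
    )
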