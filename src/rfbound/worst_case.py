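"""Exact worst-case Robinson-Foulds distances for fixed topologies.

For two tree shapes with n leaves, m_i internal edges and k_i degree-2
internal nodes, the maximum distance over all ways of labeling the leaves is

    w(T1, T2) = (m1 - k1) + (m2 - k2)

for the tree partition distance (both unrooted) and the cluster distance
(both rooted). The bound is achieved constructively: an induction on n that
at each step either deletes a leaf from a node holding >= 3 leaves, or
contracts a "cherry" (an internal node carrying exactly two leaves) into its
internal neighbour, then extends the smaller labeling with label n, patching
labels in four end-game subcases so that the two freshly created splits
cannot collide with anything on the other side.

For the unrooted-vs-rooted cluster distance (urcd) the analogous bound is
reported, but rooting an n-leaf tree on any edge creates one extra internal
node, so the achievable maximum can exceed the formula by one; construction
results carry an explicit ``bound_attained`` flag instead of asserting
equality, and the small-n exhaustive oracle is the arbiter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .tree_model import (
    PhylogeneticTree,
    TopologicalTree,
    TreeStructureError,
    shape_stats,
    suppress_degree_two,
)
from . import distances as _dist

logger = logging.getLogger(__name__)

MODES = ("tpd", "cd", "urcd")


class WorstCaseConstructionError(RuntimeError):
    """Internal verification failure: constructed labelings missed the bound.

    Never expected on valid input; signals an implementation bug.
    """


@dataclass
class WorstCaseResult:
    """A worst-case bound together with labelings verified to achieve it."""

    bound: int
    labeling1: Dict[int, int]
    labeling2: Dict[int, int]
    achieved: int
    mode: str
    tree1: PhylogeneticTree
    tree2: PhylogeneticTree

    @property
    def bound_attained(self) -> bool:
        return self.achieved == self.bound


def _score(mode: str, t1: PhylogeneticTree, t2: PhylogeneticTree) -> int:
    if mode == "tpd":
        return _dist.tpd(t1, t2)
    if mode == "cd":
        return _dist.cd(t1, t2)
    if mode == "urcd":
        return _dist.urcd(t1, t2)[0]
    raise ValueError(f"unknown mode {mode!r}")


def _check_mode_rootedness(T1: TopologicalTree, T2: TopologicalTree, mode: str) -> None:
    if mode == "tpd" and (T1.rooted or T2.rooted):
        raise TreeStructureError("tpd mode requires two unrooted trees")
    if mode == "cd" and not (T1.rooted and T2.rooted):
        raise TreeStructureError("cd mode requires two rooted trees")
    if mode == "urcd" and (T1.rooted or not T2.rooted):
        raise TreeStructureError("urcd mode requires (unrooted, rooted) trees")


def exact_bound(T1: TopologicalTree, T2: TopologicalTree, mode: str = "tpd") -> int:
    """w(T1, T2) = (m1 - k1) + (m2 - k2) from the shape statistics."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    _check_mode_rootedness(T1, T2, mode)
    s1, s2 = shape_stats(T1), shape_stats(T2)
    if s1.n != s2.n:
        raise TreeStructureError(f"leaf-count mismatch: {s1.n} != {s2.n}")
    return (s1.m - s1.k) + (s2.m - s2.k)


# ---------------------------------------------------------------------------
# the inductive construction (operates on proper working copies)
# ---------------------------------------------------------------------------


def _any_labeling(t: TopologicalTree, n: int) -> Dict[int, int]:
    return {leaf: i + 1 for i, leaf in enumerate(t.leaves())}


def _leaf_nbrs(t: TopologicalTree, v: int):
    return sorted(w for w in t.adj[v] if t.is_leaf(w))


def _node_with_ge3_leaves(t: TopologicalTree) -> Optional[int]:
    for v in t.internal_nodes():
        if len(_leaf_nbrs(t, v)) >= 3:
            return v
    return None


def _cherry_node(t: TopologicalTree) -> int:
    """Smallest internal node with exactly two leaf neighbours and exactly
    one non-leaf neighbour (exists in any proper non-star tree whose internal
    nodes all touch <= 2 leaves)."""
    for v in t.internal_nodes():
        if t.degree(v) == 3 and len(_leaf_nbrs(t, v)) == 2:
            return v
    raise WorstCaseConstructionError("no contractible cherry found")


def _contract_cherry(t: TopologicalTree, u: int, u1: int, u2: int, v: int) -> None:
    """Remove leaf u1 and node u; reconnect leaf u2 directly to v."""
    del t.adj[u1]
    del t.adj[u]
    t.adj[v].discard(u)
    t.adj[u2] = set()
    t.add_edge(u2, v)


def _base_case_n3(
    A: TopologicalTree, B: TopologicalTree
) -> Tuple[Dict[int, int], Dict[int, int]]:
    if not A.rooted:
        # the star is the unique proper unrooted 3-leaf shape; m1 = m2 = 0
        return _any_labeling(A, 3), _any_labeling(B, 3)
    ca = A.internal_nodes()
    cb = B.internal_nodes()
    if ca and cb:
        # both carry a cherry below the root: label the cherries {1,2} and
        # {1,3} so the two non-trivial clusters differ
        labA: Dict[int, int] = {}
        l1, l2 = _leaf_nbrs(A, ca[0])
        labA[l1], labA[l2] = 1, 2
        (rest,) = [l for l in A.leaves() if l not in labA]
        labA[rest] = 3
        labB: Dict[int, int] = {}
        l1, l2 = _leaf_nbrs(B, cb[0])
        labB[l1], labB[l2] = 1, 3
        (rest,) = [l for l in B.leaves() if l not in labB]
        labB[rest] = 2
        return labA, labB
    return _any_labeling(A, 3), _any_labeling(B, 3)


def _rec(
    A: TopologicalTree, B: TopologicalTree, n: int
) -> Tuple[Dict[int, int], Dict[int, int]]:
    """Labelings 1..n for proper trees A, B achieving distance mA + mB.

    Mutates A and B (they are working copies).
    """
    if n == 3:
        return _base_case_n3(A, B)

    # case 1: one tree has no internal edge (star); its split set is empty
    # for every labeling, so any labelings achieve mA + mB
    if not A.internal_edges() or not B.internal_edges():
        return _any_labeling(A, n), _any_labeling(B, n)

    a3 = _node_with_ge3_leaves(A)
    b3 = _node_with_ge3_leaves(B)

    if a3 is not None and b3 is not None:
        # case 2: delete one leaf from a >=3-leaf node on each side, recurse,
        # give label n to both deleted leaves
        la = _leaf_nbrs(A, a3)[0]
        lb = _leaf_nbrs(B, b3)[0]
        A.remove_leaf(la)
        B.remove_leaf(lb)
        labA, labB = _rec(A, B, n - 1)
        labA[la] = n
        labB[lb] = n
        return labA, labB

    # case 3: at least one tree has every internal node touching <= 2 leaves;
    # that tree drives the cherry contraction
    if a3 is None:
        return _case3(A, B, n)
    labB, labA = _case3(B, A, n)
    return labA, labB


def _case3(
    P: TopologicalTree, Q: TopologicalTree, n: int
) -> Tuple[Dict[int, int], Dict[int, int]]:
    u = _cherry_node(P)
    u1, u2 = _leaf_nbrs(P, u)
    (v,) = [w for w in P.adj[u] if not P.is_leaf(w)]
    _contract_cherry(P, u, u1, u2, v)

    q3 = _node_with_ge3_leaves(Q)
    if q3 is not None:
        # the other tree loses a leaf from a >=3-leaf node; the new cherry
        # split {n, i} in P cannot collide with Q, where every split holding
        # n has >= 3 members
        x1 = _leaf_nbrs(Q, q3)[0]
        Q.remove_leaf(x1)
        labP, labQ = _rec(P, Q, n - 1)
        labP[u1] = n
        labQ[x1] = n
        return labP, labQ

    # both trees all-<=2: contract a cherry in Q as well
    x = _cherry_node(Q)
    x1, x2 = _leaf_nbrs(Q, x)
    (y,) = [w for w in Q.adj[x] if not Q.is_leaf(w)]
    _contract_cherry(Q, x, x1, x2, y)

    # subcase facts are about the contracted (n-1)-leaf trees; snapshot them
    # now, because the recursion mutates P and Q further
    v_leaves = _leaf_nbrs(P, v)
    y_leaves = _leaf_nbrs(Q, y)

    labP, labQ = _rec(P, Q, n - 1)
    i, j = labP[u2], labQ[x2]

    if i == j:
        if len(v_leaves) >= 2:
            # subcases a/b: swap u2 with a sibling leaf under v (same-node
            # leaves are interchangeable, so the recursive distance holds)
            w = next(l for l in v_leaves if l != u2)
            labP[u2], labP[w] = labP[w], labP[u2]
        elif len(y_leaves) >= 2:
            # subcase c: mirror swap on the Q side
            w = next(l for l in y_leaves if l != x2)
            labQ[x2], labQ[w] = labQ[w], labQ[x2]
        else:
            # subcase d with equal labels: give n to both new leaves, then in
            # P only exchange labels n and k (smallest label != i)
            labP[u1] = n
            labQ[x1] = n
            k = 1 if i != 1 else 2
            leaf_k = next(l for l, lab in labP.items() if lab == k)
            labP[leaf_k] = n
            labP[u1] = k
            return labP, labQ

    labP[u1] = n
    labQ[x1] = n
    return labP, labQ


# ---------------------------------------------------------------------------
# public constructions
# ---------------------------------------------------------------------------


def _construct_same_kind(
    T1: TopologicalTree, T2: TopologicalTree, mode: str
) -> WorstCaseResult:
    bound = exact_bound(T1, T2, mode)
    n = T1.n_leaves()
    if n < 3:
        raise TreeStructureError("n must be >= 3")
    # improper inputs: suppress degree-2 chains first; leaves are untouched,
    # so the labelings transfer back verbatim
    P1, _ = suppress_degree_two(T1)
    P2, _ = suppress_degree_two(T2)
    lab1, lab2 = _rec(P1.copy(), P2.copy(), n)
    t1 = PhylogeneticTree(topology=T1.copy(), labeling=lab1)
    t2 = PhylogeneticTree(topology=T2.copy(), labeling=lab2)
    achieved = _score(mode, t1, t2)
    if achieved != bound:
        raise WorstCaseConstructionError(
            f"constructed labelings achieve {achieved}, bound is {bound}"
        )
    return WorstCaseResult(
        bound=bound,
        labeling1=lab1,
        labeling2=lab2,
        achieved=achieved,
        mode=mode,
        tree1=t1,
        tree2=t2,
    )


def construct_unrooted(T1: TopologicalTree, T2: TopologicalTree) -> WorstCaseResult:
    """Labelings achieving the worst-case tree partition distance."""
    return _construct_same_kind(T1, T2, "tpd")


def construct_rooted(T1: TopologicalTree, T2: TopologicalTree) -> WorstCaseResult:
    """Labelings achieving the worst-case cluster distance."""
    return _construct_same_kind(T1, T2, "cd")


def construct_urcd(T1: TopologicalTree, T2: TopologicalTree) -> WorstCaseResult:
    """Labelings maximizing the unrooted cluster distance, via a rooting.

    T1 is rooted on its smallest canonical edge, the rooted construction is
    run against T2, and the labeling is transferred back (rooting never
    touches leaves). ``achieved`` is the genuine min-over-all-rootings
    distance, which can differ from the (m1-k1)+(m2-k2) formula by one in
    either direction: rooting adds one internal node (pushing the true
    worst case up), while for some shape pairs every labeling admits a
    rooting that matches a cluster (pulling it down). A diagnostic is
    logged instead of failing when formula and achieved value differ.
    """
    bound = exact_bound(T1, T2, "urcd")
    e = T1.edges()[0]
    rooted_copy = T1.copy()
    r = rooted_copy.subdivide_edge(*e)
    rooted_copy.rooted = True
    rooted_copy.root = r
    inner = construct_rooted(rooted_copy, T2)
    lab1 = dict(inner.labeling1)  # leaf set identical to T1's
    t1 = PhylogeneticTree(topology=T1.copy(), labeling=lab1)
    t2 = inner.tree2
    achieved, _ = _dist.urcd(t1, t2)
    if achieved != bound:
        logger.warning(
            "urcd worst case: achieved %d differs from formula bound %d "
            "(the formula is off by at most one for urcd; see construct_urcd docs)",
            achieved,
            bound,
        )
    return WorstCaseResult(
        bound=bound,
        labeling1=lab1,
        labeling2=dict(inner.labeling2),
        achieved=achieved,
        mode="urcd",
        tree1=t1,
        tree2=t2,
    )


def construct(T1: TopologicalTree, T2: TopologicalTree, mode: str) -> WorstCaseResult:
    if mode == "tpd":
        return construct_unrooted(T1, T2)
    if mode == "cd":
        return construct_rooted(T1, T2)
    if mode == "urcd":
        return construct_urcd(T1, T2)
    raise ValueError(f"mode must be one of {MODES}")


def verify(result: WorstCaseResult, T1: TopologicalTree, T2: TopologicalTree) -> bool:
    """Recompute the distance from the stored labelings; True iff it equals
    the stored bound. Pure check, no side effects."""
    t1 = PhylogeneticTree(topology=T1.copy(), labeling=dict(result.labeling1))
    t2 = PhylogeneticTree(topology=T2.copy(), labeling=dict(result.labeling2))
    return _score(result.mode, t1, t2) == result.bound


def report(result: WorstCaseResult, T1: TopologicalTree, T2: TopologicalTree) -> str:
    """Key-value report: n, m1, k1, m2, k2, bound, achieved, mode."""
    s1, s2 = shape_stats(T1), shape_stats(T2)
    lines = [
        f"mode\t{result.mode}",
        f"n\t{s1.n}",
        f"m1\t{s1.m}",
        f"k1\t{s1.k}",
        f"m2\t{s2.m}",
        f"k2\t{s2.k}",
        f"bound\t{result.bound}",
        f"achieved\t{result.achieved}",
        f"bound_attained\t{str(result.bound_attained).lower()}",
    ]
    return "\n".join(lines)
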