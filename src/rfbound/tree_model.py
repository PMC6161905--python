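"""Tree data structures, Newick I/O and topology generation.

Trees here are undirected graphs with optional root. A *leaf* is a degree-1
node; an *internal node* is any non-leaf node, except that in a rooted tree
the root is never counted as internal. An *internal edge* is an edge not
incident to a leaf. A tree is *proper* when every internal node has degree
>= 3 (degree-2 internal nodes -- unifurcations -- are legal but improper;
the root is exempt and only needs degree >= 2).

The structural statistics (n leaves, m internal edges, k degree-2 internal
nodes) are the quantities the worst-case distance bound is built from.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Set, Tuple

import dendropy

logger = logging.getLogger(__name__)

Edge = Tuple[int, int]  # canonical: (min(u, v), max(u, v))


class TreeStructureError(ValueError):
    """Raised for structurally invalid trees or invalid tree operations."""


class NewickParseError(ValueError):
    """Raised when Newick input cannot be interpreted as a valid tree."""


def edge_key(u: int, v: int) -> Edge:
    return (u, v) if u < v else (v, u)


@dataclass
class TopologicalTree:
    """Unlabeled tree shape: adjacency sets over integer node ids.

    ``rooted`` marks one node as root; the root must have degree >= 2 and is
    never treated as an internal node.
    """

    adj: Dict[int, Set[int]] = field(default_factory=dict)
    rooted: bool = False
    root: Optional[int] = None

    # -- basic accessors -------------------------------------------------

    @property
    def nodes(self) -> List[int]:
        return list(self.adj)

    def degree(self, v: int) -> int:
        return len(self.adj[v])

    def is_leaf(self, v: int) -> bool:
        return len(self.adj[v]) == 1

    def is_internal(self, v: int) -> bool:
        return not self.is_leaf(v) and not (self.rooted and v == self.root)

    def leaves(self) -> List[int]:
        return sorted(v for v in self.adj if len(self.adj[v]) == 1)

    def internal_nodes(self) -> List[int]:
        return sorted(v for v in self.adj if self.is_internal(v))

    def edges(self) -> List[Edge]:
        return sorted(
            edge_key(u, v) for u in self.adj for v in self.adj[u] if u < v
        )

    def internal_edges(self) -> List[Edge]:
        return [
            (u, v)
            for (u, v) in self.edges()
            if not self.is_leaf(u) and not self.is_leaf(v)
        ]

    def n_leaves(self) -> int:
        return sum(1 for v in self.adj if len(self.adj[v]) == 1)

    # -- mutation helpers (used by generators and the worst-case search) --

    def new_node_id(self) -> int:
        return max(self.adj, default=-1) + 1

    def add_edge(self, u: int, v: int) -> None:
        self.adj.setdefault(u, set()).add(v)
        self.adj.setdefault(v, set()).add(u)

    def remove_leaf(self, v: int) -> None:
        (nbr,) = self.adj[v]
        self.adj[nbr].discard(v)
        del self.adj[v]

    def subdivide_edge(self, u: int, v: int) -> int:
        """Replace edge {u,v} by a path u - w - v; return the new node w."""
        if v not in self.adj[u]:
            raise TreeStructureError(f"edge {(u, v)} not in tree")
        w = self.new_node_id()
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.adj[w] = {u, v}
        self.adj[u].add(w)
        self.adj[v].add(w)
        return w

    def contract_edge(self, u: int, v: int) -> None:
        """Merge v into u (both must be non-leaves; root survives)."""
        if self.rooted and v == self.root:
            u, v = v, u
        self.adj[u].discard(v)
        for w in self.adj.pop(v):
            if w != u:
                self.adj[w].discard(v)
                self.adj[w].add(u)
                self.adj[u].add(w)

    def copy(self) -> "TopologicalTree":
        return TopologicalTree(
            adj={v: set(nbrs) for v, nbrs in self.adj.items()},
            rooted=self.rooted,
            root=self.root,
        )

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        n_nodes = len(self.adj)
        n_edges = sum(len(nbrs) for nbrs in self.adj.values())
        if n_edges % 2:
            raise TreeStructureError("asymmetric adjacency")
        if n_edges // 2 != n_nodes - 1:
            raise TreeStructureError("edge count != node count - 1")
        # connectivity; acyclicity follows from the edge count
        seen = set()
        stack = [next(iter(self.adj))]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(self.adj[v] - seen)
        if len(seen) != n_nodes:
            raise TreeStructureError("tree is not connected")
        if self.rooted:
            if self.root not in self.adj:
                raise TreeStructureError("root not a node of the tree")
            if len(self.adj[self.root]) < 2:
                raise TreeStructureError("root must have degree >= 2")
        if self.n_leaves() < 3:
            raise TreeStructureError("trees must have at least 3 leaves")

    # -- orientation (rooted trees) --------------------------------------

    def parent_map(self) -> Dict[int, Optional[int]]:
        """Parent of each node when oriented away from the root."""
        if not self.rooted:
            raise TreeStructureError("parent_map requires a rooted tree")
        parent: Dict[int, Optional[int]] = {self.root: None}
        stack = [self.root]
        while stack:
            v = stack.pop()
            for w in self.adj[v]:
                if w not in parent:
                    parent[w] = v
                    stack.append(w)
        return parent


@dataclass(frozen=True)
class TreeShapeStats:
    """(n, m, k) of a tree: leaves, internal edges, degree-2 internal nodes."""

    n: int
    m: int
    k: int
    proper: bool


@dataclass
class PhylogeneticTree:
    """A topology plus a bijective leaf labeling over {1..n}.

    ``taxon_map`` optionally maps each integer label to an external taxon
    name; labels are assigned 1..n in lexicographic name order on parse.
    """

    topology: TopologicalTree
    labeling: Dict[int, int]
    taxon_map: Optional[Dict[int, str]] = None

    @property
    def n(self) -> int:
        return len(self.labeling)

    def validate(self) -> None:
        self.topology.validate()
        leaves = set(self.topology.leaves())
        if set(self.labeling) != leaves:
            raise TreeStructureError("labeling domain is not the leaf set")
        if sorted(self.labeling.values()) != list(range(1, len(leaves) + 1)):
            raise TreeStructureError("labels are not a bijection onto 1..n")

    def label_of(self, leaf: int) -> int:
        return self.labeling[leaf]

    def leaf_with_label(self, label: int) -> int:
        for leaf, lab in self.labeling.items():
            if lab == label:
                return leaf
        raise KeyError(label)

    def copy(self) -> "PhylogeneticTree":
        return PhylogeneticTree(
            topology=self.topology.copy(),
            labeling=dict(self.labeling),
            taxon_map=dict(self.taxon_map) if self.taxon_map else None,
        )


# ---------------------------------------------------------------------------
# structural statistics
# ---------------------------------------------------------------------------


def shape_stats(tree: TopologicalTree) -> TreeShapeStats:
    """Count n (leaves), m (internal edges), k (degree-2 internal nodes)."""
    n = tree.n_leaves()
    m = len(tree.internal_edges())
    k = sum(1 for v in tree.internal_nodes() if tree.degree(v) == 2)
    proper = k == 0 and all(tree.degree(v) >= 3 for v in tree.internal_nodes())
    return TreeShapeStats(n=n, m=m, k=k, proper=proper)


# ---------------------------------------------------------------------------
# degree-2 suppression
# ---------------------------------------------------------------------------


def suppress_degree_two(tree):
    """Collapse every maximal path of degree-2 internal nodes to one edge.

    Accepts a TopologicalTree or PhylogeneticTree; returns ``(tree',
    correspondence)`` where correspondence maps each surviving node to its
    original id (identity: suppression only deletes nodes). Leaves and, in
    rooted trees, the root are never suppressed, so labelings carry over
    unchanged. The bipartition/cluster set of the tree is invariant.
    """
    if isinstance(tree, PhylogeneticTree):
        topo, corr = suppress_degree_two(tree.topology)
        return (
            PhylogeneticTree(
                topology=topo,
                labeling=dict(tree.labeling),
                taxon_map=dict(tree.taxon_map) if tree.taxon_map else None,
            ),
            corr,
        )
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for v in list(t.adj):
            if v in t.adj and t.degree(v) == 2 and t.is_internal(v):
                a, b = t.adj[v]
                del t.adj[v]
                t.adj[a].discard(v)
                t.adj[b].discard(v)
                t.add_edge(a, b)
                changed = True
    return t, {v: v for v in t.adj}


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------


def root_on_edge(tree: PhylogeneticTree, e: Edge) -> PhylogeneticTree:
    """Root an unrooted tree by subdividing edge ``e`` with a new root node."""
    if tree.topology.rooted:
        raise TreeStructureError("root_on_edge requires an unrooted tree")
    u, v = e
    if v not in tree.topology.adj.get(u, set()):
        raise TreeStructureError(f"edge {e} not in tree")
    topo = tree.topology.copy()
    r = topo.subdivide_edge(u, v)
    topo.rooted = True
    topo.root = r
    return PhylogeneticTree(
        topology=topo,
        labeling=dict(tree.labeling),
        taxon_map=dict(tree.taxon_map) if tree.taxon_map else None,
    )


# ---------------------------------------------------------------------------
# Newick I/O (via dendropy)
# ---------------------------------------------------------------------------


def read_newick(text: str, mode: str = "unrooted") -> PhylogeneticTree:
    """Parse a Newick string into a PhylogeneticTree.

    In ``unrooted`` mode the top-level node is an ordinary node: a top-level
    bifurcation yields a degree-2 node which is kept (suppression is an
    explicit, separate operation). Leaf names must be unique; labels 1..n
    are assigned in lexicographic name order and the names retained in
    ``taxon_map``. Branch lengths are discarded (the metrics are purely
    topological). Single-child Newick clauses become degree-2 nodes.
    """
    if mode not in ("unrooted", "rooted"):
        raise ValueError(f"mode must be 'unrooted' or 'rooted', got {mode!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise NewickParseError(f"Newick parse failure: {exc}") from exc

    if any(nd.edge.length is not None for nd in dtree):
        logger.info("branch lengths present in input; discarded (topological metrics only)")

    topo = TopologicalTree(rooted=(mode == "rooted"))
    ids: Dict[object, int] = {}
    names: Dict[int, str] = {}
    for nd in dtree.preorder_node_iter():
        vid = len(ids)
        ids[nd] = vid
        topo.adj[vid] = set()
        if nd.parent_node is not None:
            topo.add_edge(ids[nd.parent_node], vid)
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise NewickParseError("leaf without a name")
            names[vid] = nd.taxon.label

    leaf_ids = [v for v in topo.adj if len(topo.adj[v]) <= 1 and v in names]
    if len(set(names.values())) != len(names):
        raise NewickParseError("duplicate leaf names")
    if len(leaf_ids) < 3:
        raise NewickParseError("fewer than 3 leaves")
    for v in topo.adj:
        if len(topo.adj[v]) <= 1 and v not in names:
            raise NewickParseError("unnamed degree-1 node (dangling unifurcation)")

    if mode == "rooted":
        topo.root = ids[dtree.seed_node]
        if topo.degree(topo.root) < 2:
            raise NewickParseError("rooted mode requires top-level degree >= 2")

    order = sorted(leaf_ids, key=lambda v: names[v])
    labeling = {v: i + 1 for i, v in enumerate(order)}
    taxon_map = {labeling[v]: names[v] for v in leaf_ids}
    tree = PhylogeneticTree(topology=topo, labeling=labeling, taxon_map=taxon_map)
    tree.validate()
    return tree


def write_newick(tree: PhylogeneticTree) -> str:
    """Serialize to Newick; read(write(t)) is isomorphic to t.

    Unrooted trees are written from an internal node of degree >= 3 when one
    exists (top-level multifurcation); degree-2 chains appear as single-child
    clauses. Leaves without taxon names are written as zero-padded label
    strings so the lexicographic relabeling on re-parse reproduces the
    original labeling.
    """
    topo = tree.topology
    if topo.rooted:
        start = topo.root
    else:
        candidates = [v for v in topo.internal_nodes() if topo.degree(v) >= 3]
        start = min(candidates) if candidates else min(topo.internal_nodes())

    width = len(str(tree.n))

    def name_of(leaf: int) -> str:
        if tree.taxon_map:
            return tree.taxon_map[tree.labeling[leaf]]
        return f"t{tree.labeling[leaf]:0{width}d}"

    tns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=tns)

    def build(v: int, parent: Optional[int], dnode) -> None:
        for w in sorted(topo.adj[v]):
            if w == parent:
                continue
            child = dnode.new_child()
            if topo.is_leaf(w):
                child.taxon = tns.require_taxon(label=name_of(w))
            else:
                build(w, v, child)

    build(start, None, dtree.seed_node)
    out = dtree.as_string(schema="newick", suppress_rooting=True)
    return out.strip()


# ---------------------------------------------------------------------------
# canonical forms (AHU) for isomorphism tests and deterministic choices
# ---------------------------------------------------------------------------


def canonical_rooted(tree: TopologicalTree, root: Optional[int] = None) -> str:
    if root is None:
        root = tree.root
        if root is None:
            raise TreeStructureError("canonical_rooted needs a root")

    def enc(v: int, parent: Optional[int]) -> str:
        kids = sorted(
            enc(w, v) for w in tree.adj[v] if w != parent
        )
        return "(" + "".join(kids) + ")"

    return enc(root, None)


def canonical_form(tree: TopologicalTree) -> str:
    """Isomorphism-invariant string; rooted trees canonize from the root,
    unrooted trees minimize the rooted form over all possible start nodes."""
    if tree.rooted:
        return "r" + canonical_rooted(tree, tree.root)
    return "u" + min(canonical_rooted(tree, v) for v in tree.adj)


# ---------------------------------------------------------------------------
# random topology generation
# ---------------------------------------------------------------------------


def random_topology(
    n: int,
    rooted: bool = False,
    resolution: float = 1.0,
    k: int = 0,
    seed: Optional[int] = None,
) -> TopologicalTree:
    """Random tree shape: n leaves, multifurcation level set by ``resolution``,
    plus ``k`` inserted degree-2 nodes.

    A uniform random binary shape is grown by sequential leaf attachment to a
    uniformly chosen edge; a (1 - resolution) fraction of internal edges is
    then contracted; finally k uniformly chosen edges (leaf edges included)
    are subdivided. Deterministic given ``seed``.
    """
    if n < 3:
        raise TreeStructureError("n must be >= 3")
    if not 0.0 <= resolution <= 1.0:
        raise ValueError("resolution must be in [0, 1]")
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = random.Random(seed)

    t = TopologicalTree(rooted=rooted)
    if rooted:
        t.adj = {0: {1, 2}, 1: {0}, 2: {0}}
        t.root = 0
        start_leaves = 2
    else:
        t.adj = {0: {1, 2, 3}, 1: {0}, 2: {0}, 3: {0}}
        start_leaves = 3
    for _ in range(n - start_leaves):
        u, v = rng.choice(t.edges())
        w = t.subdivide_edge(u, v)
        leaf = t.new_node_id()
        t.add_edge(w, leaf)

    m_full = len(t.internal_edges())
    n_contract = round((1.0 - resolution) * m_full)
    for _ in range(n_contract):
        internal = t.internal_edges()
        if not internal:
            break
        u, v = rng.choice(internal)
        t.contract_edge(u, v)

    for _ in range(k):
        u, v = rng.choice(t.edges())
        t.subdivide_edge(u, v)

    t.validate()
    return t


# ---------------------------------------------------------------------------
# exhaustive topology enumeration (small n; oracle support)
# ---------------------------------------------------------------------------

ENUMERATION_CAP = 7


class CapExceededError(ValueError):
    """Raised when an exhaustive operation is asked beyond its size cap."""


def _rooted_shape_tuples(n: int, min_children: int = 2) -> List[tuple]:
    """Canonical nested tuples for rooted shapes with n leaves where every
    non-leaf node has >= 2 children and the root has >= min_children."""

    def partitions(total: int, max_part: int, min_len: int) -> Iterator[Tuple[int, ...]]:
        def rec(remaining: int, cap: int, acc: List[int]) -> Iterator[Tuple[int, ...]]:
            if remaining == 0:
                yield tuple(acc)
                return
            for part in range(min(cap, remaining), 0, -1):
                acc.append(part)
                yield from rec(remaining - part, part, acc)
                acc.pop()

        for p in rec(total, max_part, []):
            if len(p) >= min_len:
                yield p

    def shapes(size: int) -> List[tuple]:
        if size == 1:
            return [()]  # a leaf
        out: Set[tuple] = set()
        for part in partitions(size, size - 1, 2):
            # group equal part sizes; choose multisets of subshapes per group
            groups: List[Tuple[int, int]] = []
            for sz, grp in itertools.groupby(part):
                groups.append((sz, len(list(grp))))
            pools = [
                list(itertools.combinations_with_replacement(shapes(sz), cnt))
                for sz, cnt in groups
            ]
            for combo in itertools.product(*pools):
                children = tuple(sorted(itertools.chain.from_iterable(combo)))
                out.add(children)
        return sorted(out)

    result = []
    for shape in shapes(n):
        if len(shape) >= min_children:
            result.append(shape)
    return result


def _tuple_to_tree(shape: tuple, rooted: bool) -> TopologicalTree:
    t = TopologicalTree(rooted=rooted)
    counter = itertools.count()

    def build(node_shape: tuple, parent: Optional[int]) -> int:
        vid = next(counter)
        t.adj[vid] = set()
        if parent is not None:
            t.add_edge(parent, vid)
        for child in node_shape:
            build(child, vid)
        return vid

    root = build(shape, None)
    if rooted:
        t.root = root
    return t


def _insert_degree_two_variants(
    base: TopologicalTree, max_k: int
) -> Iterator[TopologicalTree]:
    """All shapes reachable from ``base`` by 1..max_k edge subdivisions
    (chains on one edge included), one per isomorphism class."""
    frontier = {canonical_form(base): base}
    for _ in range(max_k):
        nxt: Dict[str, TopologicalTree] = {}
        for t in frontier.values():
            for (u, v) in t.edges():
                t2 = t.copy()
                t2.subdivide_edge(u, v)
                nxt.setdefault(canonical_form(t2), t2)
        frontier = nxt
        yield from frontier.values()


def enumerate_topologies(
    n: int,
    rooted: bool = False,
    proper_only: bool = True,
    max_unifurcations: int = 0,
    cap: int = ENUMERATION_CAP,
) -> List[TopologicalTree]:
    """One representative per isomorphism class of tree shapes with n leaves.

    With ``proper_only=False``, shapes carrying up to ``max_unifurcations``
    inserted degree-2 nodes are included as well (the improper classes are
    infinite without such a bound). Deduplication is by AHU canonical form.
    """
    if n > cap:
        raise CapExceededError(f"n={n} exceeds enumeration cap {cap}")
    if n < 3:
        raise TreeStructureError("n must be >= 3")

    proper: List[TopologicalTree] = []
    seen: Set[str] = set()
    if rooted:
        for shape in _rooted_shape_tuples(n, min_children=2):
            t = _tuple_to_tree(shape, rooted=True)
            key = canonical_form(t)
            if key not in seen:
                seen.add(key)
                proper.append(t)
    else:
        # root a proper unrooted tree at any internal node: >=3 children
        # there, >=2 children elsewhere; dedupe over rootings
        for shape in _rooted_shape_tuples(n, min_children=3):
            t = _tuple_to_tree(shape, rooted=False)
            key = canonical_form(t)
            if key not in seen:
                seen.add(key)
                proper.append(t)

    if proper_only or max_unifurcations == 0:
        return proper

    out = list(proper)
    for base in proper:
        for t in _insert_degree_two_variants(base, max_unifurcations):
            key = canonical_form(t)
            if key not in seen:
                seen.add(key)
                out.append(t)
    return out


def label_canonically(topo: TopologicalTree) -> PhylogeneticTree:
    """Attach labels 1..n to leaves in sorted node-id order."""
    leaves = topo.leaves()
    return PhylogeneticTree(
        topology=topo.copy(),
        labeling={v: i + 1 for i, v in enumerate(leaves)},
    )
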